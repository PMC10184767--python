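"""Treatment statistics on the extracted trial table.

For each kinematic variable: a linear mixed model (swim speed covariate,
viscosity × light × lateral-line fixed effects with two-way interactions,
per-fish random intercept, per-viscosity residual variances where they
differ), estimated-marginal-means pairwise contrasts with Bonferroni
correction, an outlier screen on studentized residuals, and a two-sided
exact test on the pectoral fin-state counts per condition.

Run after 02_extract_kinematics.py:  python analysis/03_fit_models.py
"""

import warnings
from pathlib import Path

import pandas as pd

from swimkin.exceptions import SwimkinError
from swimkin.stats import (
    contrasts_frame,
    emmeans_contrasts,
    fisher_exact,
    fit_variable_model,
    screen_outliers,
)

OUT = Path("results")
VARIABLES = [
    "swim_speed_U",
    "fin_freq",
    "tail_amp_A",
    "wave_freq_f",
    "wave_speed_V",
    "wavelength_lambda",
]


def main():
    table = pd.read_csv(OUT / "trials.csv")
    table = table[table.rejection_reason.fillna("") == ""]
    print(f"fitting on {len(table)} accepted trials")
    all_contrasts = []
    summaries = []
    for var in VARIABLES:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_variable_model(table, var, variance_groups="viscosity")
        except SwimkinError as exc:
            print(f"{var}: skipped ({exc})")
            continue
        summaries.append(fit.summary())
        cons = emmeans_contrasts(fit)
        all_contrasts.extend(cons)
        sig = [c for c in cons if c.significant]
        print(
            f"{var:18s} n={fit.n_obs:2d}  "
            + (
                "significant: " + ", ".join(f"{c.factor}" for c in sig)
                if sig
                else "no significant contrasts"
            )
        )
        flags = screen_outliers(table, var, fit=fit)
        if flags.outlier_flag.any():
            print(
                f"  {int(flags.outlier_flag.sum())} candidate outlier(s) — "
                "inspect before removal, never dropped silently"
            )
    (OUT / "model_summaries.txt").write_text("\n\n".join(summaries) + "\n")
    contrasts_frame(all_contrasts).to_csv(OUT / "contrasts.csv", index=False)

    lines = []
    for factor in ("viscosity", "light", "lateral_line"):
        ct = pd.crosstab(table["fin_state"], table[factor])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact(ct.to_numpy())
        line = f"fin state × {factor}: two-sided exact p = {p:.4g}"
        lines.extend([line, ct.to_string(), ""])
        print(line)
    (OUT / "fin_state_tests.txt").write_text("\n".join(lines))
    print(f"wrote model summaries, contrasts and fin-state tests to {OUT}/")


if __name__ == "__main__":
    main()
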