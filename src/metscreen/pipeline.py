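"""Full-analysis orchestration.

``run_full_analysis`` chains the stages — cohort (generated or read from
CSV), index panel, NCEP ATP III diagnosis, ROC battery, association table —
and writes plain-CSV reports plus a JSON run manifest.  Identical inputs,
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from metscreen.association import DEFAULT_ADJUSTMENT, dichotomize_index, odds_ratio_table
from metscreen.cohort import COVARIATE_NAMES, default_config, generate_cohort
from metscreen.indices import INDEX_NAMES, panel_frame
from metscreen.io import read_cohort_csv
from metscreen.mets import COMPONENT_NAMES, diagnose_cohort
from metscreen.roc import run_roc_battery

__all__ = ["RunConfig", "descriptive_table", "run_full_analysis"]


@dataclass
class RunConfig:
    """One analysis run: exactly one cohort source, plus output options."""

    output_dir: str
    seed: int = 0
    input_path: str | None = None
    unit_declarations: dict[str, str] | None = None
    n: int | None = None  # generator size; defaults to the calibrated 9457
    adjustment: tuple[str, ...] = DEFAULT_ADJUSTMENT
    outcomes: tuple[str, ...] = ("mets",) + COMPONENT_NAMES

    def validate(self) -> None:
        if (self.input_path is None) == (self.n is None) and self.input_path is None:
            # neither source given -> fall back to generator default size
            return
        if self.input_path is not None and self.n is not None:
            raise ValueError("give either input_path or a generator size n, not both")
        if self.input_path is not None and not self.unit_declarations:
            raise ValueError("reading a cohort CSV requires unit declarations")


def descriptive_table(
    cohort: pd.DataFrame,
    strata_col: str = "sex",
    continuous: tuple[str, ...] = ("age", "height", "weight", "wc", "tg", "hdl", "fpg", "sbp", "dbp"),
    categorical: tuple[str, ...] = COVARIATE_NAMES,
) -> pd.DataFrame:
    """Stratified baseline-characteristics table.

    Continuous rows report mean ± SD per stratum with a pooled-variance
    two-sample t-test p-value; categorical rows report n (%) per level with
    a chi-square test (no continuity correction, so two identical strata
    give a zero statistic and p = 1).  Comparisons are only made between
    exactly two strata; with any other number the p column is NaN.
    """
    strata = [s for s, _ in cohort.groupby(strata_col, observed=True)]
    groups = {s: g for s, g in cohort.groupby(strata_col, observed=True)}
    two = len(strata) == 2 and all(len(groups[s]) >= 2 for s in strata)
    rows = []
    for col in continuous:
        row = {"variable": col, "level": ""}
        for s in strata:
            vals = groups[s][col].astype(float)
            row[f"{s}"] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
        if two:
            a, b = (groups[s][col].astype(float) for s in strata)
            row["p"] = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        else:
            row["p"] = np.nan
        rows.append(row)
    for col in categorical:
        if col not in cohort.columns:
            continue
        table = pd.crosstab(cohort[col], cohort[strata_col])
        if two and table.shape[0] > 1:
            chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        else:
            p = np.nan
        first = True
        for level in table.index:
            row = {"variable": col, "level": str(level)}
            for s in strata:
                n = int(table.loc[level, s]) if s in table.columns else 0
                total = len(groups[s])
                row[f"{s}"] = f"{n} ({100.0 * n / total:.2f}%)"
            row["p"] = float(p) if first else np.nan
            first = False
            rows.append(row)
    return pd.DataFrame(rows)


def _log(message: str, t0: float) -> None:
    print(f"[metscreen +{time.perf_counter() - t0:6.2f}s] {message}", file=sys.stderr)


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle.

    Writes to ``config.output_dir``: ``cohort.csv`` (generated runs only),
    ``prevalence.csv``, ``roc_cutpoints.csv``, ``associations.csv``,
    ``rejects.csv``, ``descriptives.csv`` and ``manifest.json``.  Returns a
    name -> path mapping.
    """
    config.validate()
    t0 = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    from metscreen import __version__ as version

    manifest: dict = {"seed": config.seed, "version": version}

    if config.input_path is not None:
        raw = Path(config.input_path).read_bytes()
        manifest["input_sha256"] = hashlib.sha256(raw).hexdigest()
        cohort, rejects = read_cohort_csv(config.input_path, config.unit_declarations)
        _log(f"read {len(cohort)} records, {len(rejects)} rejects", t0)
    else:
        n = config.n or 9457
        cohort, gen_report = generate_cohort(default_config(n=n, seed=config.seed))
        rejects = pd.DataFrame(columns=["id", "reason"])
        manifest["generator"] = {"n": n, **gen_report}
        paths["cohort"] = out / "cohort.csv"
        cohort.to_csv(paths["cohort"], index=False)
        _log(f"generated {len(cohort)} records", t0)

    panels = panel_frame(cohort)
    flags, prevalence = diagnose_cohort(cohort)
    _log(f"diagnosed: overall prevalence {prevalence.iloc[0]['prevalence_percent']}%", t0)

    roc_table = run_roc_battery(cohort, panels, flags["mets"])
    _log("ROC battery done (13 indices x 2 sexes)", t0)

    cutoffs = {
        (r.sex_stratum, r.index_name): r.optimal_cutoff
        for r in roc_table.itertuples()
        if r.error == ""
    }
    exposures = pd.DataFrame(index=cohort.index)
    for name in INDEX_NAMES:
        col = np.full(len(cohort), False)
        for sex in ("male", "female"):
            mask = (cohort["sex"] == sex).to_numpy()
            if (sex, name) in cutoffs:
                col[mask] = dichotomize_index(
                    panels.loc[mask, name].to_numpy(), cutoffs[(sex, name)]
                )
        exposures[name] = col
    outcomes = flags[[c for c in config.outcomes]].copy()
    adjustment = tuple(c for c in config.adjustment if c != "sex")
    assoc = odds_ratio_table(cohort, exposures, outcomes, covariates=adjustment)
    _log("association table done", t0)

    reports = {
        "prevalence": prevalence,
        "roc_cutpoints": roc_table,
        "associations": assoc,
        "rejects": rejects,
        "descriptives": descriptive_table(cohort),
    }
    for name, frame in reports.items():
        paths[name] = out / f"{name}.csv"
        frame.to_csv(paths[name], index=False, float_format="%.6g")
    paths["manifest"] = out / "manifest.json"
    manifest["reports"] = sorted(reports)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log("reports written", t0)
    return paths
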