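"""Cohort-level statistical program.

Runs the full analysis battery on a scored cohort table: for each outcome
(mRS, NIHSS) three nested proportional-odds models —

* baseline:                ``outcome ~ age + sex + age:sex + dwiv_cc``
* rich-club:               ``outcome ~ age + sex + age:sex + dwiv_cc + n_rc
  + dwiv_cc:n_rc``
* rich-club w/o interactions: ``outcome ~ age + sex + dwiv_cc + n_rc``

— compared by likelihood ratio (ANOVA chi-square) and AIC, plus the
no-rich-club-involvement subgroup analysis with ``n_total`` replacing
``n_rc``, standard diagnostics (VIF, Spearman), and a repeated k-fold
stability analysis of the coefficient estimates: the cohort is split
``repetitions`` times into k near-equal disjoint folds and the model is
refit on each leave-one-fold-out subset (no held-out evaluation — the
point is the spread of the odds ratios, not prediction error).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import pearson, spearman, vif
from .exceptions import (
    ConfigurationError,
    DegenerateOutcomeError,
    InputError,
    StabilityError,
    SubgroupError,
)
from .ordinal import (
    CumulativeLinkModel,
    CumulativeLinkResults,
    DesignSpec,
    ModelComparison,
    lrt_compare,
)

__all__ = [
    "MODEL_SPECS",
    "model_spec",
    "validate_cohort",
    "run_model_battery",
    "BatteryReport",
    "subgroup_no_richclub",
    "SubgroupReport",
    "repeated_cv_stability",
    "StabilityReport",
    "cohort_diagnostics",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("mrs", "nihss")
MAIN_PREDICTORS = ("age", "sex", "dwiv_cc", "n_rc")

MODEL_SPECS: dict[str, dict] = {
    "baseline": dict(
        main_terms=("age", "sex", "dwiv_cc"),
        interaction_terms=(("age", "sex"),),
    ),
    "richclub": dict(
        main_terms=("age", "sex", "dwiv_cc", "n_rc"),
        interaction_terms=(("age", "sex"), ("dwiv_cc", "n_rc")),
    ),
    "richclub-nointer": dict(
        main_terms=("age", "sex", "dwiv_cc", "n_rc"),
        interaction_terms=(),
    ),
    "subgroup-ntotal": dict(
        main_terms=("age", "sex", "dwiv_cc", "n_total"),
        interaction_terms=(("age", "sex"), ("dwiv_cc", "n_total")),
    ),
}


def model_spec(name: str, outcome: str) -> DesignSpec:
    if name not in MODEL_SPECS:
        raise ConfigurationError(
            f"unknown model {name!r}; choose from {sorted(MODEL_SPECS)}"
        )
    cfg = MODEL_SPECS[name]
    return DesignSpec(
        outcome=outcome,
        main_terms=tuple(cfg["main_terms"]),
        interaction_terms=tuple(cfg["interaction_terms"]),
    )


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Range/consistency checks on a scored cohort table."""
    required = {"age", "sex", "dwiv_cc", "n_rc", "n_total", "nihss", "mrs"}
    missing = required - set(cohort.columns)
    if missing:
        raise InputError(f"cohort is missing columns: {sorted(missing)}")
    sub = cohort[sorted(required)]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise InputError(f"missing values in rows {bad[:20]}")
    checks = [
        ((cohort["n_rc"] < 0) | (cohort["n_rc"] > 12), "n_rc outside 0-12"),
        (cohort["n_total"] < cohort["n_rc"], "n_total < n_rc"),
        ((cohort["mrs"] < 0) | (cohort["mrs"] > 6), "mrs outside 0-6"),
        ((cohort["nihss"] < 0) | (cohort["nihss"] > 42), "nihss outside 0-42"),
        (cohort["dwiv_cc"] < 0, "negative dwiv_cc"),
    ]
    for bad, reason in checks:
        if bad.any():
            raise InputError(f"{reason} in rows {cohort.index[bad].tolist()[:20]}")
    return cohort


# ----------------------------------------------------------------------
# model battery
# ----------------------------------------------------------------------

@dataclass
class BatteryReport:
    """Per-outcome nested-model fits with LRT comparisons and OR tables."""

    fits: dict[str, dict[str, CumulativeLinkResults]]
    comparisons: dict[str, dict[str, ModelComparison]]

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for outcome, models in self.fits.items():
            for name, res in models.items():
                row = {"outcome": outcome, "model": name}
                for term, b, se, p in zip(res.term_names, res.params,
                                          res.bse, res.pvalues):
                    row[term] = f"{b:.2f} ± {se:.2f}"
                    row[f"{term}_p"] = p
                row["aic"] = res.aic
                row["loglik"] = res.llf
                rows.append(row)
        return pd.DataFrame(rows)

    def or_table(self, model: str = "richclub", alpha: float = 0.05) -> pd.DataFrame:
        frames = []
        for outcome, models in self.fits.items():
            tab = models[model].odds_ratios(alpha=alpha)
            tab.insert(0, "outcome", outcome)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.coefficient_table().to_csv(path, sep="\t", index=False)


def _fit(cohort: pd.DataFrame, name: str, outcome: str) -> CumulativeLinkResults:
    return CumulativeLinkModel.from_spec(cohort, model_spec(name, outcome)).fit()


def run_model_battery(cohort: pd.DataFrame,
                      outcomes=OUTCOMES) -> BatteryReport:
    """Fit baseline / rich-club / rich-club-no-interaction for each outcome.

    Comparisons: baseline vs rich-club, and rich-club-no-interaction vs
    rich-club (both via likelihood ratio).  A degenerate rich-club model
    (e.g. ``n_rc`` identically zero) is reported as such rather than
    silently fitted.
    """
    validate_cohort(cohort)
    fits: dict[str, dict[str, CumulativeLinkResults]] = {}
    comps: dict[str, dict[str, ModelComparison]] = {}
    for outcome in outcomes:
        if np.ptp(cohort["n_rc"].to_numpy()) == 0:
            raise DegenerateOutcomeError(
                "n_rc is constant in this cohort; the rich-club model is "
                "degenerate (fit the baseline model only)"
            )
        fits[outcome] = {
            name: _fit(cohort, name, outcome)
            for name in ("baseline", "richclub", "richclub-nointer")
        }
        comps[outcome] = {
            "baseline_vs_richclub": lrt_compare(
                fits[outcome]["baseline"], fits[outcome]["richclub"]
            ),
            "nointer_vs_richclub": lrt_compare(
                fits[outcome]["richclub-nointer"], fits[outcome]["richclub"]
            ),
        }
    return BatteryReport(fits=fits, comparisons=comps)


# ----------------------------------------------------------------------
# subgroup: no rich-club involvement
# ----------------------------------------------------------------------

@dataclass
class SubgroupReport:
    n: int
    fits: dict[str, CumulativeLinkResults]
    pearson_dwiv_ntotal: float

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for outcome, res in self.fits.items():
            row = {"outcome": outcome}
            for term, b, se, p in zip(res.term_names, res.params,
                                      res.bse, res.pvalues):
                row[term] = f"{b:.2f} ± {se:.2f}"
                row[f"{term}_p"] = p
            rows.append(row)
        return pd.DataFrame(rows)


def subgroup_no_richclub(cohort: pd.DataFrame,
                         outcomes=OUTCOMES) -> SubgroupReport:
    """Refit with ``n_total`` on the patients without rich-club involvement.

    Tests whether a plain count of affected regions carries outcome
    information once the rich-club is untouched.
    """
    validate_cohort(cohort)
    sub = cohort.loc[cohort["n_rc"] == 0].copy()
    if sub.empty:
        raise SubgroupError("no patients without rich-club involvement")
    if len(sub) < 30:
        logger.warning("subgroup has only %d rows; estimates will be unstable",
                       len(sub))
    fits = {
        outcome: _fit(sub, "subgroup-ntotal", outcome) for outcome in outcomes
    }
    return SubgroupReport(
        n=len(sub),
        fits=fits,
        pearson_dwiv_ntotal=pearson(sub["dwiv_cc"], sub["n_total"]),
    )


# ----------------------------------------------------------------------
# repeated k-fold stability
# ----------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Spread of odds ratios over repeated leave-one-fold-out refits."""

    term_names: list[str]
    mean_or: pd.Series
    sd_or: pd.Series
    n_nonsignificant: pd.Series
    total_fits: int
    skipped: int
    records: pd.DataFrame = field(repr=False)
    seed: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_or": self.mean_or,
            "sd_or": self.sd_or,
            "n_nonsignificant": self.n_nonsignificant,
            "total_fits": self.total_fits,
        })

    def to_dict(self) -> dict:
        return {
            "term_names": self.term_names,
            "mean_or": self.mean_or.to_dict(),
            "sd_or": self.sd_or.to_dict(),
            "n_nonsignificant": {k: int(v) for k, v in
                                 self.n_nonsignificant.items()},
            "total_fits": int(self.total_fits),
            "skipped": int(self.skipped),
            "seed": int(self.seed),
        }


def _fold_partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition into k disjoint covering folds, sizes differing <= 1."""
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def repeated_cv_stability(cohort: pd.DataFrame, model: str, outcome: str,
                          k: int = 5, repetitions: int = 100,
                          alpha: float = 0.05, seed: int = 0,
                          max_skip_fraction: float = 0.05) -> StabilityReport:
    """Repeated k-fold stability analysis of the coefficient estimates.

    For each of ``repetitions`` random partitions into ``k`` near-equal
    disjoint folds, the model is refit on every leave-one-fold-out subset
    (k fits per repetition, no test-fold evaluation).  Per-term odds
    ratios and Wald p-values are recorded; the report aggregates their
    mean, sd and the count of fits in which the term was *not* significant
    at ``alpha``.  Folds whose training subset has a single outcome level
    are skipped and logged; more than ``max_skip_fraction`` skipped is an
    error.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    validate_cohort(cohort)
    n = len(cohort)
    if n < 5 * k:
        raise ConfigurationError(f"need n >= 5k rows (n={n}, k={k})")
    spec = model_spec(model, outcome)
    rng = np.random.default_rng(seed)
    cohort = cohort.reset_index(drop=True)

    records = []
    skipped = 0
    for rep in range(repetitions):
        folds = _fold_partition(n, k, rng)
        for fold_idx, fold in enumerate(folds):
            train = cohort.drop(index=fold)
            if train[outcome].nunique() < 2:
                skipped += 1
                logger.warning("repetition %d fold %d skipped: degenerate outcome",
                               rep, fold_idx)
                continue
            res = CumulativeLinkModel.from_spec(train, spec).fit()
            for term, b, p in zip(res.term_names, res.params, res.pvalues):
                records.append({
                    "repetition": rep, "fold": fold_idx, "term": term,
                    "or": float(np.exp(b)), "beta": float(b), "p": float(p),
                })
    total = repetitions * k - skipped
    if skipped > max_skip_fraction * repetitions * k:
        raise StabilityError(
            f"{skipped} of {repetitions * k} fits skipped (> "
            f"{max_skip_fraction:.0%})"
        )
    rec = pd.DataFrame(records)
    grouped = rec.groupby("term", sort=False)
    return StabilityReport(
        term_names=spec.term_names,
        mean_or=grouped["or"].mean(),
        sd_or=grouped["or"].std(ddof=1),
        n_nonsignificant=grouped["p"].apply(lambda p: int((p >= alpha).sum())),
        total_fits=total,
        skipped=skipped,
        records=rec,
        seed=seed,
    )


# ----------------------------------------------------------------------
# diagnostics bundle and pipeline
# ----------------------------------------------------------------------

def cohort_diagnostics(cohort: pd.DataFrame) -> dict:
    """VIF on the main effects plus rank correlations of N_RC with outcomes."""
    validate_cohort(cohort)
    vifs = vif(cohort[list(MAIN_PREDICTORS)])
    out = {"vif": {k: float(v) for k, v in vifs.items()}, "spearman": {}}
    for outcome in OUTCOMES:
        rho, p = spearman(cohort["n_rc"], cohort[outcome])
        out["spearman"][f"n_rc_vs_{outcome}"] = {"rho": rho, "p": p}
    out["pearson_dwiv_ntotal"] = pearson(cohort["dwiv_cc"], cohort["n_total"])
    return out


def run_pipeline(config: dict, out_dir, log_stream=None) -> dict:
    """End-to-end run: simulate or ingest -> battery -> subgroup ->
    diagnostics -> stability; writes all artifacts under ``out_dir``.

    ``config`` keys: either ``cohort_csv`` (path to a scored cohort) or
    ``simulate`` (kwargs for :class:`~rcstroke.simulate.CohortConfig`),
    plus optional ``stability`` kwargs (model, outcome, k, repetitions,
    alpha, seed) and ``seed``.
    Returns a dict of the in-memory reports.
    """
    from . import __version__
    from .simulate import CohortConfig, simulate_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log_lines = [f"rcstroke {__version__}", f"seed {seed}"]

    if "cohort_csv" in config:
        cohort = pd.read_csv(config["cohort_csv"])
        log_lines.append(f"cohort ingested from {config['cohort_csv']}")
    else:
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs.setdefault("seed", seed)
        cfg = CohortConfig(**sim_kwargs)
        cohort = simulate_cohort(cfg)
        log_lines.append(f"cohort simulated: n={cfg.n} seed={cfg.seed}")
    validate_cohort(cohort)
    cohort.to_csv(out / "cohort.csv", index=False)

    battery = run_model_battery(cohort)
    battery.to_tsv(out / "model_battery.tsv")
    battery.or_table().to_csv(out / "odds_ratios.tsv", sep="\t", index=False)

    subgroup = subgroup_no_richclub(cohort)
    subgroup.coefficient_table().to_csv(out / "subgroup_ntotal.tsv",
                                        sep="\t", index=False)

    diag = cohort_diagnostics(cohort)
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))

    stab_cfg = dict(config.get("stability", {}))
    stab = repeated_cv_stability(
        cohort,
        model=stab_cfg.get("model", "richclub"),
        outcome=stab_cfg.get("outcome", "mrs"),
        k=int(stab_cfg.get("k", 5)),
        repetitions=int(stab_cfg.get("repetitions", 100)),
        alpha=float(stab_cfg.get("alpha", 0.05)),
        seed=int(stab_cfg.get("seed", seed)),
    )
    (out / "stability.json").write_text(json.dumps(stab.to_dict(), indent=2))

    comps = {
        outcome: {name: vars(c) for name, c in d.items()}
        for outcome, d in battery.comparisons.items()
    }
    log_lines += [f"comparisons: {json.dumps(comps)}"]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "cohort": cohort,
        "battery": battery,
        "subgroup": subgroup,
        "diagnostics": diag,
        "stability": stab,
    }
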