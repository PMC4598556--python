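"""End-to-end comparative analysis: trait coding, rates under several
extinction fractions, a PGLS model battery per tree, and sister-clade tests.

The analysis unit is a clade (order, family or subfamily) carrying described
species richness, a stem age, a herbivory proportion in [0, 1] and two
binary traits (wings, holometaboly). The pipeline reproduces the standard
analysis shape:

1. code herbivory proportions (richness-weighted aggregation of subunits,
   equal-frequency splits for mixed diets, clade merging);
2. method-of-moments net diversification rates at epsilon in {0, 0.5, 0.9};
3. for each tree x epsilon x model formula, a PGLS fit with ML Pagel's
   lambda, reported as a Table-style row (formula, n, lambda, r^2, P, AIC);
4. optionally, richness as the response instead of rates (natural-log
   richness, since richness is log-linear in rate x age), and the
   richness ~ rate regression;
5. sister-clade pairs differing in herbivory presence with exact one-tailed
   sign tests, pooled and per scope.

Everything is deterministic given the inputs; randomness only enters through
the synthetic-data generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import pgls, rates, sisters, trees

logger = logging.getLogger("cladediv")

#: the standard five-model battery (predictor tuples; intercept implied)
DEFAULT_FORMULAS: tuple[tuple[str, ...], ...] = (
    ("herbivory_prop",),
    ("wings",),
    ("holometaboly",),
    ("herbivory_prop", "wings"),
    ("herbivory_prop", "wings", "holometaboly"),
)

TRAIT_COLUMNS = (
    "clade_id", "richness", "stem_age_myr", "herbivory_prop",
    "wings", "holometaboly",
)


class PipelineError(ValueError):
    """Inconsistent inputs to an analysis run."""


# ---------------------------------------------------------------------------
# trait coding rules
# ---------------------------------------------------------------------------

def aggregate_herbivory(subunits: Iterable[tuple[float, float]]) -> float:
    """Richness-weighted mean herbivory fraction over (richness, fraction)
    subunits, e.g. families within an order."""
    subunits = list(subunits)
    total = sum(n for n, _ in subunits)
    if total <= 0:
        raise PipelineError("total richness is 0; cannot aggregate herbivory")
    for n, f in subunits:
        if n < 0 or not (0.0 <= f <= 1.0):
            raise PipelineError(f"invalid subunit (richness={n}, fraction={f})")
    return sum(n * f for n, f in subunits) / total


def code_mixed_diet(feeding_types: Sequence[str]) -> float:
    """Herbivory fraction for a clade listing several feeding types.

    Feeding types are assumed equally frequent, so the fraction is the share
    of entries equal to "herbivory". Xylophagy (dead/woody tissue) counts as
    a distinct, non-herbivorous diet: herbivory covers feeding on living
    vascular-plant tissue only.
    """
    if not feeding_types:
        raise PipelineError("empty feeding-type list")
    kinds = [ft.strip().lower() for ft in feeding_types]
    return kinds.count("herbivory") / len(kinds)


def merge_clades(
    records: pd.DataFrame,
    merge_map: Mapping[str, Mapping],
) -> pd.DataFrame:
    """Amalgamate terminal units (e.g. subfamilies into their family).

    ``merge_map`` maps a new clade id to ``{"members": [ids...],
    "stem_age_myr": age}`` — the merged unit's stem age must be supplied
    (the family's, from the tree), since member stem ages refer to shallower
    splits. Richness is summed, herbivory is richness-weighted, and binary
    traits are OR-combined. Records not mentioned pass through unchanged.
    """
    records = records.copy()
    merged_rows = []
    drop: set = set()
    for new_id, spec in merge_map.items():
        members = list(spec["members"])
        if "stem_age_myr" not in spec or pd.isna(spec["stem_age_myr"]):
            raise PipelineError(f"merged clade '{new_id}' needs a stem age")
        sub = records[records["clade_id"].isin(members)]
        if len(sub) != len(members):
            missing = set(members) - set(sub["clade_id"])
            raise PipelineError(f"merge members not found: {sorted(missing)}")
        row = {
            "clade_id": new_id,
            "richness": int(sub["richness"].sum()),
            "stem_age_myr": float(spec["stem_age_myr"]),
            "herbivory_prop": aggregate_herbivory(
                zip(sub["richness"], sub["herbivory_prop"])
            ),
        }
        for col in ("wings", "holometaboly"):
            if col in records.columns:
                row[col] = int(sub[col].max())
        if "diet_known" in records.columns:
            row["diet_known"] = bool(sub["diet_known"].all())
        merged_rows.append(row)
        drop.update(members)
    out = pd.concat(
        [records[~records["clade_id"].isin(drop)], pd.DataFrame(merged_rows)],
        ignore_index=True,
    )
    return out


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """One full analysis run over one or more candidate trees."""

    trees: dict[str, trees.TimeTree]      # label -> tree
    traits: pd.DataFrame                  # TRAIT_COLUMNS (+ diet_known, order)
    epsilons: Sequence[float] = rates.CANONICAL_EPSILONS
    formulas: Sequence[Sequence[str]] = DEFAULT_FORMULAS
    response: str = "rate"                # "rate" or "log_richness"
    richness_vs_rate: bool = False        # add log_richness ~ rate fits
    herb_threshold: float = 0.0           # herbivory-presence cutoff for sisters
    clade_map: Mapping[str, Iterable[str]] | None = None  # tip -> clade pruning
    seed: int = 0

    def __post_init__(self):
        missing = set(TRAIT_COLUMNS) - set(self.traits.columns)
        if missing:
            raise PipelineError(f"trait table missing columns: {sorted(missing)}")
        if self.response not in ("rate", "log_richness"):
            raise PipelineError(f"unknown response {self.response!r}")
        known = set(self.traits.columns)
        for f in self.formulas:
            unknown = set(f) - known
            if unknown:
                raise PipelineError(f"formula references unknown columns: {sorted(unknown)}")


def _usable_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Drop diet-unknown and incomplete records, logging each exclusion."""
    out = traits
    if "diet_known" in out.columns:
        bad = ~out["diet_known"].astype(bool)
        if bad.any():
            for cid in out.loc[bad, "clade_id"]:
                logger.warning("excluding clade %r: diet unknown", cid)
            out = out[~bad]
    complete = out[list(TRAIT_COLUMNS)].notna().all(axis=1)
    if (~complete).any():
        for cid in out.loc[~complete, "clade_id"]:
            logger.warning("excluding clade %r: incomplete record", cid)
        out = out[complete]
    return out.reset_index(drop=True)


def _clade_tree(tree: trees.TimeTree, cfg: AnalysisConfig,
                clade_ids: Sequence[str]) -> trees.TimeTree:
    """Prune to exemplars if a clade map is given, then check tip/clade match."""
    if cfg.clade_map is not None:
        tree = trees.prune_to_exemplars(tree, cfg.clade_map)
    tips, want = set(tree.tip_labels), set(clade_ids)
    if tips != want:
        diff = sorted(tips ^ want)
        raise PipelineError(
            f"tree tips and trait clades differ (symmetric difference: {diff})"
        )
    return tree


# ---------------------------------------------------------------------------
# PGLS battery
# ---------------------------------------------------------------------------

def run_order_analysis(cfg: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the model battery for every tree x epsilon x formula.

    Returns ``(models, coefficients)``: one row per fitted model with
    formula, n, lambda-hat, r^2, model P and AIC; and a long table of
    per-coefficient estimates, SEs and P values.
    """
    traits = _usable_traits(cfg.traits)
    if traits.empty:
        raise PipelineError("no usable clade records")
    model_rows, coef_rows = [], []
    for label, tree in cfg.trees.items():
        clade_tree = _clade_tree(tree, cfg, traits["clade_id"])
        C = trees.vcv_matrix(clade_tree)
        data = traits.set_index("clade_id").loc[list(C.taxa)]

        eps_iter = list(cfg.epsilons)
        if cfg.response == "log_richness" and not cfg.richness_vs_rate:
            eps_iter = [None]  # response does not involve rates
        for eps in eps_iter:
            data_eps = data.copy()
            if eps is not None:
                data_eps["rate"] = [
                    rates.mom_stem_rate(int(r), float(t), eps)
                    for r, t in zip(data_eps["richness"], data_eps["stem_age_myr"])
                ]
            data_eps["log_richness"] = np.log(data_eps["richness"].astype(float))
            y = data_eps[cfg.response]

            fits = []
            for formula in cfg.formulas:
                X = data_eps[list(formula)].astype(float)
                fit = pgls.profile_lambda_ml(y, X, C, response=cfg.response)
                fits.append((formula, fit))
            if cfg.richness_vs_rate:
                X = data_eps[["rate"]]
                fits.append((
                    ("rate",),
                    pgls.profile_lambda_ml(
                        data_eps["log_richness"], X, C, response="log_richness"
                    ),
                ))
            for formula, fit in fits:
                model_rows.append({
                    "tree": label,
                    "epsilon": eps,
                    "formula": fit.formula(),
                    "n": fit.n,
                    "lambda_hat": fit.lambda_hat,
                    "r_squared": fit.r_squared,
                    "model_P": fit.model_P,
                    "aic": fit.aic,
                    "logL": fit.logL,
                })
                for name in fit.params.index:
                    coef_rows.append({
                        "tree": label,
                        "epsilon": eps,
                        "formula": fit.formula(),
                        "term": name,
                        "estimate": fit.params[name],
                        "se": fit.bse[name],
                        "t": fit.tvalues[name],
                        "P": fit.pvalues[name],
                    })
    return pd.DataFrame(model_rows), pd.DataFrame(coef_rows)


# ---------------------------------------------------------------------------
# sister-clade analysis
# ---------------------------------------------------------------------------

def run_sister_analysis(
    cfg: AnalysisConfig, tree_label: str | None = None
) -> dict:
    """Extract sister pairs and run sign tests, pooled and per scope.

    Scopes come from an optional ``order`` column in the trait table: pairs
    are extracted separately within each order's induced subtree, plus one
    pooled extraction over the whole tree. Returns ``{"pairs": DataFrame,
    "tests": {scope: SignTestResult}}``; an empty pair set yields an empty
    table rather than an error.
    """
    traits = _usable_traits(cfg.traits)
    label = tree_label or next(iter(cfg.trees))
    tree = _clade_tree(cfg.trees[label], cfg, traits["clade_id"])
    herb = dict(zip(traits["clade_id"], traits["herbivory_prop"]))
    rich = dict(zip(traits["clade_id"], traits["richness"].astype(int)))

    scopes: dict[str, list[str]] = {"pooled": list(traits["clade_id"])}
    if "order" in traits.columns:
        for order, sub in traits.groupby("order"):
            if len(sub) >= 2:
                scopes[str(order)] = list(sub["clade_id"])

    pair_rows, tests = [], {}
    for scope, clades in scopes.items():
        if scope == "pooled":
            scope_tree = tree
        else:
            scope_tree = trees.restrict_to_tips(tree, clades)
        pairs = sisters.extract_sister_pairs(
            scope_tree, herb, rich, threshold=cfg.herb_threshold
        )
        for p in pairs:
            pair_rows.append({
                "scope": scope,
                "clade_herb": "+".join(p.clade_herb),
                "clade_nonherb": "+".join(p.clade_nonherb),
                "richness_herb": p.richness_herb,
                "richness_nonherb": p.richness_nonherb,
                "stem_age_myr": p.stem_age,
                "herb_richer": p.herb_richer,
            })
        if pairs:
            try:
                tests[scope] = sisters.pair_summary(pairs)
            except sisters.SisterError as exc:
                logger.info("scope %s: %s", scope, exc)
    columns = ["scope", "clade_herb", "clade_nonherb", "richness_herb",
               "richness_nonherb", "stem_age_myr", "herb_richer"]
    return {"pairs": pd.DataFrame(pair_rows, columns=columns), "tests": tests}


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(df: pd.DataFrame, path: str | Path,
                 header: Mapping | None = None) -> None:
    """Write a TSV report with provenance key=value comment lines on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {k} = {v}" for k, v in (header or {}).items()]
    body = df.to_csv(sep="\t", index=False, float_format="%.10g")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a delimited clade trait table (TSV/CSV sniffed by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineError(f"trait table missing columns: {sorted(missing)}")
    return df
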