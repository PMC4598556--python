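"""Method-of-moments net diversification rates from stem ages and richness.

For a clade with n extant described species and stem age t (Myr), the
method-of-moments estimator under a relative extinction fraction
epsilon = mu/lambda is

    r_hat = ln(n (1 - eps) + eps) / t        [lineages / Myr, natural log]

With eps = 0 this is ln(n)/t; a monotypic clade (n = 1) always gives 0.
epsilon is applied globally per analysis run, conventionally at
{0, 0.5, 0.9} (none, intermediate, high extinction).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cladediv")

#: canonical relative extinction fractions
CANONICAL_EPSILONS = (0.0, 0.5, 0.9)


def mom_stem_rate(n: int | float, t: float, eps: float = 0.0) -> float:
    """Net diversification rate (lineages/Myr) from stem age and richness.

    Parameters
    ----------
    n : int
        Described extant species richness of the clade (>= 1).
    t : float
        Stem age in Myr (> 0).
    eps : float
        Relative extinction fraction mu/lambda, in [0, 1).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if not (0.0 <= eps < 1.0):
        raise ValueError(f"eps must be in [0, 1), got {eps}")
    return math.log(n * (1.0 - eps) + eps) / t


def rate_table(
    records: pd.DataFrame,
    eps_list: Sequence[float] = CANONICAL_EPSILONS,
) -> pd.DataFrame:
    """Per-clade rates for each extinction fraction, one row per clade x eps.

    ``records`` needs columns ``clade_id``, ``richness``, ``stem_age_myr``.
    Rows with missing or invalid richness/age are excluded with a logged
    reason (mirroring the exclusion of clades lacking usable data) rather
    than aborting the run. Input columns are carried through for audit.
    """
    required = {"clade_id", "richness", "stem_age_myr"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    for eps in eps_list:
        if not (0.0 <= eps < 1.0):
            raise ValueError(f"eps must be in [0, 1), got {eps}")

    rows = []
    n_excluded = 0
    for rec in records.itertuples(index=False):
        problem = _row_problem(rec)
        if problem:
            n_excluded += 1
            logger.warning("excluding clade %r: %s", rec.clade_id, problem)
            continue
        for eps in eps_list:
            rows.append({
                "clade_id": rec.clade_id,
                "richness": int(rec.richness),
                "stem_age_myr": float(rec.stem_age_myr),
                "epsilon": eps,
                "rate": mom_stem_rate(int(rec.richness), float(rec.stem_age_myr), eps),
            })
    if n_excluded:
        logger.info("rate_table: excluded %d of %d clades", n_excluded, len(records))
    return pd.DataFrame(
        rows, columns=["clade_id", "richness", "stem_age_myr", "epsilon", "rate"]
    )


def _row_problem(rec) -> str | None:
    if pd.isna(rec.richness):
        return "missing richness"
    if pd.isna(rec.stem_age_myr):
        return "missing stem age"
    if rec.richness < 1:
        return f"richness < 1 ({rec.richness})"
    if rec.stem_age_myr <= 0:
        return f"stem age <= 0 ({rec.stem_age_myr})"
    return None


def richness_from_rate(rate: float, t: float, eps: float = 0.0) -> float:
    """Invert the estimator: expected richness implied by a rate and age.

    For eps = 0 this is exp(rate * t); the general inverse of
    ``mom_stem_rate`` is (exp(rate * t) - eps) / (1 - eps).
    """
    if not (0.0 <= eps < 1.0):
        raise ValueError(f"eps must be in [0, 1), got {eps}")
    return (math.exp(rate * t) - eps) / (1.0 - eps)
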