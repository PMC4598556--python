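"""Sister-clade comparisons: least-inclusive pairs differing in herbivory
presence, and exact one-tailed sign tests on species richness.

Sister clades are the two daughter lineages of one node, so they share a
stem age by construction; a richness difference between them therefore
implies a net diversification-rate difference. A pair is informative when
herbivory is present (any proportion above the threshold, default 0) in
exactly one member. Pairs are extracted tip-ward (least inclusive first) and
never overlap. Under the null that herbivory is irrelevant, the herbivorous
member wins each richness comparison with probability 1/2, giving an exact
binomial sign test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from scipy import stats

from .trees import PolytomyError, TimeTree

logger = logging.getLogger("cladediv")


class SisterError(ValueError):
    """Invalid input to sister-pair extraction or the sign test."""


@dataclass(frozen=True)
class SisterPair:
    """Two sister clades, one containing herbivory and one without."""

    node_id: str                 # id of the MRCA joining the pair
    clade_herb: tuple[str, ...]  # tips of the clade containing herbivory
    clade_nonherb: tuple[str, ...]
    richness_herb: int
    richness_nonherb: int
    stem_age: float              # shared stem age of the two clades (Myr)

    @property
    def herb_richer(self) -> bool | None:
        """True/False for a strict winner, None for a richness tie."""
        if self.richness_herb == self.richness_nonherb:
            return None
        return self.richness_herb > self.richness_nonherb


@dataclass(frozen=True)
class SignTestResult:
    n_pairs: int       # informative (non-tied) pairs
    k_success: int     # pairs where the herbivorous clade is strictly richer
    ties: int
    p_one_tailed: float


def sign_test(k: int, n: int) -> float:
    """Exact one-tailed binomial sign test: P(X >= k), X ~ Binomial(n, 1/2).

    This is the upper tail sum_{i=k..n} C(n, i) / 2^n.
    """
    if n < 1:
        raise SisterError("no informative pairs (n = 0)")
    if not (0 <= k <= n):
        raise SisterError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, 0.5))


def extract_sister_pairs(
    tree: TimeTree,
    herb_state: Mapping[str, bool | float],
    richness: Mapping[str, int],
    threshold: float = 0.0,
) -> list[SisterPair]:
    """Non-overlapping, least-inclusive sister pairs differing in herbivory.

    ``herb_state`` maps each tip to a boolean or to a herbivory proportion
    (present when proportion > ``threshold``). ``richness`` maps each tip to
    its described species count; a clade's richness is the sum over its tips.

    The tree is traversed post-order (tips first). A node yields a pair when
    one child subtree is entirely herbivory-free, the other contains
    herbivory, and no tip of either subtree already belongs to a reported
    pair. Post-order guarantees that nested candidates resolve to the pair
    closest to the tips, and that reported clades never overlap.
    """
    tips = set(tree.tip_labels)
    missing = sorted(tips - set(herb_state))
    if missing:
        raise SisterError(f"tips missing herbivory state: {missing}")
    missing = sorted(tips - set(richness))
    if missing:
        raise SisterError(f"tips missing richness: {missing}")
    if not tree.is_binary:
        raise PolytomyError(
            "sister-pair extraction requires a strictly bifurcating tree"
        )

    present = {t: float(herb_state[t]) > threshold for t in tips}

    pairs: list[SisterPair] = []
    used: set[str] = set()
    info: dict = {}  # node -> (sorted tip tuple, any_present, all_absent)
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            info[node] = ((lab,), present[lab], not present[lab])
            continue
        c1, c2 = node.child_nodes()
        tips1, any1, absent1 = info[c1]
        tips2, any2, absent2 = info[c2]
        info[node] = (
            tuple(sorted(tips1 + tips2)), any1 or any2, absent1 and absent2
        )
        if used.intersection(tips1) or used.intersection(tips2):
            continue
        if absent1 and any2:
            herb_tips, non_tips, herb_node = tips2, tips1, c2
        elif absent2 and any1:
            herb_tips, non_tips, herb_node = tips1, tips2, c1
        else:
            continue
        pairs.append(SisterPair(
            node_id="|".join(sorted((herb_tips[0], non_tips[0]))),
            clade_herb=herb_tips,
            clade_nonherb=non_tips,
            richness_herb=sum(richness[t] for t in herb_tips),
            richness_nonherb=sum(richness[t] for t in non_tips),
            stem_age=tree.node_age(node),
        ))
        used.update(herb_tips)
        used.update(non_tips)
    return pairs


def pair_summary(pairs: list[SisterPair]) -> SignTestResult:
    """Aggregate pairs into an exact one-tailed sign test on richness.

    Successes are pairs in which the herbivory-containing clade is strictly
    richer; richness ties are dropped from n (and logged).
    """
    if not pairs:
        raise SisterError("no sister pairs to summarize")
    ties = sum(1 for p in pairs if p.herb_richer is None)
    k = sum(1 for p in pairs if p.herb_richer is True)
    n = len(pairs) - ties
    if ties:
        logger.info("pair_summary: dropped %d richness tie(s) from n", ties)
    if n == 0:
        raise SisterError("no informative pairs (all richness ties)")
    return SignTestResult(
        n_pairs=n, k_success=k, ties=ties, p_one_tailed=sign_test(k, n)
    )
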