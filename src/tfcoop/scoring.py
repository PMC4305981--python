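"""Cooperativity scoring.

For every unordered TF pair the score combines two log-space tail
probabilities:

* the hypergeometric probability of observing at least the seen number of
  common target genes given the two target-set sizes and the gene universe;
* the one-sided Fisher-exact probability of observing at least the seen
  number of co-depleted promoters in the 2x2 nucleosome-occupancy table
  built over the pair's shared-target promoters.

score = -log10(P_overlap) - log10(P_nu).  Both tails are evaluated with
log-gamma binomial coefficients and log-sum-exp, so p-values far below
float underflow still produce finite scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .data import DataError, NucleosomeTrack, PairResult, TFBSRecord, canonical_pair
from .targets import BestSiteIndex, TargetGeneSets

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 120.0

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Nucleosome-occupancy 2x2 table over a pair's shared-site promoters.

    a: both sites depleted; b: first occupied / second depleted;
    c: first depleted / second occupied; d: both occupied.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


def _log_comb(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    out = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    return np.where((k < 0) | (k > n), -np.inf, out)


def _hypergeom_tail_log10(n1: int, n2: int, m: int, total: int) -> float:
    """log10 P(X >= m) for X ~ Hypergeometric(total, n1, n2)."""
    support_min = max(0, n1 + n2 - total)
    if m <= support_min:  # tail spans the whole distribution
        return 0.0
    lo = max(m, support_min)
    hi = min(n1, n2)
    if lo > hi:  # only possible when m exceeds the support, guarded upstream
        return -math.inf
    i = np.arange(lo, hi + 1)
    log_terms = _log_comb(n1, i) + _log_comb(total - n1, n2 - i) - _log_comb(total, n2)
    log_p = float(logsumexp(log_terms))
    # the full sum can exceed 0 by rounding; the tail is a probability
    return min(log_p / _LN10, 0.0)


def overlap_pvalue(n1: int, n2: int, m: int, total_genes: int) -> tuple[float, float]:
    """Tail probability of >= m shared targets; returns (p, log10 p).

    ``p`` underflows to 0.0 below ~1e-308; ``log10 p`` is always finite.
    """
    for name, v in (("n1", n1), ("n2", n2), ("m", m), ("total_genes", total_genes)):
        if v < 0:
            raise DataError(f"{name} must be non-negative, got {v}")
    if m > min(n1, n2):
        raise DataError(f"m={m} exceeds min(n1, n2)={min(n1, n2)}")
    if max(n1, n2) > total_genes:
        raise DataError(f"target-set size exceeds total_genes={total_genes}")
    log10_p = _hypergeom_tail_log10(n1, n2, m, total_genes)
    return 10.0 ** log10_p, log10_p


def codepletion_pvalue(table: ContingencyTable) -> tuple[float, float]:
    """One-sided Fisher tail favoring co-depletion; returns (p, log10 p).

    Sums the hypergeometric term from the observed both-depleted count
    upward with margins fixed.  A degenerate table (empty, or a zero
    margin makes the observed cell the only outcome) yields p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        return 1.0, 0.0
    log10_p = _hypergeom_tail_log10(a + b, a + c, a, n)
    return 10.0 ** log10_p, log10_p


def occupancy_state(site: TFBSRecord, track: NucleosomeTrack) -> int:
    """1 if any base of the site lies in an occupied interval, else 0."""
    if site.chrom not in track.chroms:
        logger.debug("chromosome %s absent from nucleosome track; site treated "
                     "as depleted", site.chrom)
        return 0
    return 1 if track.overlaps(site.chrom, site.start, site.end) else 0


def build_contingency(
    tf1: str,
    tf2: str,
    targets: TargetGeneSets,
    best_sites: BestSiteIndex,
    track: NucleosomeTrack,
) -> tuple[frozenset[str], ContingencyTable]:
    """Classify each shared-target promoter carrying both TFs' best sites.

    Returns the gene set (common targets with a best site for BOTH TFs)
    and the occupancy table over it.
    """
    if tf1 == tf2:
        raise DataError(f"cannot build a contingency table for {tf1} with itself")
    common = targets[tf1] & targets[tf2]
    set_a = frozenset(
        g for g in common if (tf1, g) in best_sites and (tf2, g) in best_sites
    )
    a = b = c = d = 0
    for gene in set_a:
        s1 = occupancy_state(best_sites[(tf1, gene)], track)
        s2 = occupancy_state(best_sites[(tf2, gene)], track)
        if s1 == 0 and s2 == 0:
            a += 1
        elif s1 == 1 and s2 == 0:
            b += 1
        elif s1 == 0 and s2 == 1:
            c += 1
        else:
            d += 1
    return set_a, ContingencyTable(a, b, c, d)


def cooperativity_score(log10_p_overlap: float, log10_p_nu: float) -> float:
    """-log10 P_overlap - log10 P_nu from log-space inputs."""
    for v in (log10_p_overlap, log10_p_nu):
        if v > 0:
            raise DataError(f"log10 p-value must be <= 0, got {v}")
    return -(log10_p_overlap + log10_p_nu)


def score_pair(
    tf1: str,
    tf2: str,
    targets: TargetGeneSets,
    best_sites: BestSiteIndex,
    track: NucleosomeTrack,
    *,
    disable_nucleosome: bool = False,
) -> PairResult:
    tf1, tf2 = canonical_pair(tf1, tf2)
    t1, t2 = targets[tf1], targets[tf2]
    m = len(t1 & t2)
    p_ov, log10_p_ov = overlap_pvalue(len(t1), len(t2), m, targets.total_genes)
    _, table = build_contingency(tf1, tf2, targets, best_sites, track)
    if disable_nucleosome:
        p_nu, log10_p_nu = 1.0, 0.0
    else:
        p_nu, log10_p_nu = codepletion_pvalue(table)
    return PairResult(
        tf1=tf1, tf2=tf2, n1=len(t1), n2=len(t2), m=m,
        p_overlap=p_ov, log10_p_overlap=log10_p_ov,
        a=table.a, b=table.b, c=table.c, d=table.d,
        p_nu=p_nu, log10_p_nu=log10_p_nu,
        score=cooperativity_score(log10_p_ov, log10_p_nu),
    )


def score_all_pairs(
    targets: TargetGeneSets,
    best_sites: BestSiteIndex,
    track: NucleosomeTrack,
    *,
    disable_nucleosome: bool = False,
) -> list[PairResult]:
    """Score every unordered TF pair; rank by score desc, then pair name."""
    from .targets import enumerate_pairs

    results = [
        score_pair(tf1, tf2, targets, best_sites, track,
                   disable_nucleosome=disable_nucleosome)
        for tf1, tf2 in enumerate_pairs(targets)
    ]
    results.sort(key=lambda r: (-r.score, r.tf1, r.tf2))
    return results


def predict(
    results: Sequence[PairResult], score_threshold: float = DEFAULT_SCORE_THRESHOLD
) -> list[PairResult]:
    """Pairs scoring strictly above the threshold, rank order preserved."""
    return [r for r in results if r.score > score_threshold]


def export_network(
    predicted: Iterable,
    path,
    annotations: Optional[Mapping[str, Iterable[str]]] = None,
) -> None:
    """Write predicted pairs as a TSV edge list.

    ``annotations`` maps TF -> categories; each edge is labelled with the
    pair's shared categories (empty when none).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf1\ttf2\tshared_categories\n")
        for item in predicted:
            tf1, tf2 = item.pair if isinstance(item, PairResult) else canonical_pair(*item)
            shared = ""
            if annotations is not None:
                cats1 = set(annotations.get(tf1, ()))
                cats2 = set(annotations.get(tf2, ()))
                shared = ";".join(sorted(cats1 & cats2))
            fh.write(f"{tf1}\t{tf2}\t{shared}\n")
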