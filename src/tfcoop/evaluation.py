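"""Benchmark-based evaluation of predicted TF pairs.

Three quantities are provided: the mean significance of PPI-partner
overlap across a prediction list, the significance of the list's overlap
with a benchmark of known cooperative pairs, and plain precision/recall.
A pluggable hook averages an externally supplied functional-similarity
score; no similarity measure is shipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .data import BenchmarkSet, DataError, PairAnnotationRow, PPINetwork, canonical_pair
from .scoring import ContingencyTable, codepletion_pvalue, overlap_pvalue

logger = logging.getLogger(__name__)

# the PPI-partner index text fixes its own gene-universe size, one less
# than the one used for target-overlap significance
DEFAULT_PPI_UNIVERSE = 6575
DEFAULT_PAIR_UNIVERSE = 17205


@dataclass(frozen=True)
class EvaluationReport:
    index1_mean: float
    index3_score: float
    precision: float
    recall: float
    per_pair_index1: tuple[float, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "index1_mean": self.index1_mean,
            "index3_score": self.index3_score,
            "precision": self.precision,
            "recall": self.recall,
        }


@dataclass(frozen=True)
class EvidenceSummary:
    """Counts of evidence lines across an annotation table.

    The three lines per pair are: existing-method citation, documented
    PPI, and shared MIPS category membership.
    """

    n_rows: int
    n_consistent_with_existing: int
    n_novel: int
    n_all_three_lines: int
    n_two_lines: int
    n_one_line: int
    novel_with_ppi_and_mips: int


def _as_pairs(items: Iterable) -> list[tuple[str, str]]:
    out = []
    for item in items:
        pair = item.pair if hasattr(item, "pair") else canonical_pair(*item)
        out.append(pair)
    return out


def ppi_partner_overlap_score(
    tf1: str,
    tf2: str,
    ppi: PPINetwork,
    total_genes: int = DEFAULT_PPI_UNIVERSE,
) -> float:
    """-log10 of the hypergeometric tail for shared-PPI-partner count.

    TFs absent from the network have empty partner sets, giving p = 1 and
    a score of 0.
    """
    p1 = ppi.partners(tf1)
    p2 = ppi.partners(tf2)
    m = len(p1 & p2)
    _, log10_p = overlap_pvalue(len(p1), len(p2), m, total_genes)
    return -log10_p


def index1(
    predicted: Sequence,
    ppi: PPINetwork,
    total_genes: int = DEFAULT_PPI_UNIVERSE,
) -> tuple[float, list[float]]:
    """Mean PPI-partner-overlap score over a prediction list."""
    pairs = _as_pairs(predicted)
    if not pairs:
        raise DataError("cannot evaluate an empty prediction list")
    scores = [ppi_partner_overlap_score(a, b, ppi, total_genes) for a, b in pairs]
    return sum(scores) / len(scores), scores


def index3(
    predicted: Sequence,
    benchmark: BenchmarkSet,
    pair_universe: int = DEFAULT_PAIR_UNIVERSE,
    tf_universe: Optional[set[str]] = None,
) -> float:
    """-log10 Fisher-exact enrichment of the prediction in the benchmark.

    The 2x2 table (in both, predicted only, benchmark only, neither) is
    built over ``pair_universe`` unordered pairs.  Benchmark pairs whose
    TFs fall outside ``tf_universe`` (when given) are dropped with a
    warning, since the method could never have predicted them.
    """
    pred = set(_as_pairs(predicted))
    bench = set(benchmark.pairs)
    if tf_universe is not None:
        universe = {t.upper() for t in tf_universe}
        dropped = {p for p in bench if not (p[0] in universe and p[1] in universe)}
        if dropped:
            logger.warning(
                "dropping %d benchmark pairs outside the TF universe", len(dropped)
            )
            bench -= dropped
    if pair_universe < len(pred | bench):
        raise DataError(
            f"pair universe {pair_universe} smaller than the "
            f"{len(pred | bench)} observed pairs"
        )
    both = len(pred & bench)
    table = ContingencyTable(
        a=both,
        b=len(pred) - both,
        c=len(bench) - both,
        d=pair_universe - len(pred | bench),
    )
    _, log10_p = codepletion_pvalue(table)
    return -log10_p


def precision_recall(
    predicted: Sequence, benchmark: BenchmarkSet
) -> tuple[float, float]:
    """Unordered-pair precision and recall against the benchmark."""
    pred = set(_as_pairs(predicted))
    if not pred:
        raise DataError("precision is undefined for an empty prediction list")
    if not benchmark.pairs:
        raise DataError("recall is undefined for an empty benchmark")
    hits = len(pred & benchmark.pairs)
    return hits / len(pred), hits / len(benchmark.pairs)


def summarize_evidence(rows: Sequence[PairAnnotationRow]) -> EvidenceSummary:
    """Tally evidence lines per row of an annotation table."""
    counts = {1: 0, 2: 0, 3: 0}
    n_cited = 0
    n_novel = 0
    novel_both = 0
    for row in rows:
        lines = (
            int(bool(row.method_citations))
            + int(row.has_ppi)
            + int(bool(row.mips_categories))
        )
        if lines in counts:
            counts[lines] += 1
        if row.method_citations:
            n_cited += 1
        else:
            n_novel += 1
            if row.has_ppi and row.mips_categories:
                novel_both += 1
    return EvidenceSummary(
        n_rows=len(rows),
        n_consistent_with_existing=n_cited,
        n_novel=n_novel,
        n_all_three_lines=counts[3],
        n_two_lines=counts[2],
        n_one_line=counts[1],
        novel_with_ppi_and_mips=novel_both,
    )


def functional_similarity_hook(
    provider: Callable[[tuple[str, str]], float], predicted: Sequence
) -> float:
    """Mean of an external pair-scoring function over a prediction list."""
    pairs = _as_pairs(predicted)
    if not pairs:
        raise DataError("cannot evaluate an empty prediction list")
    scores = []
    for pair in pairs:
        try:
            scores.append(float(provider(pair)))
        except Exception as exc:
            raise DataError(f"similarity provider failed on pair {pair}: {exc}") from exc
    return sum(scores) / len(scores)


def identity_provider(pair: tuple[str, str]) -> float:
    """Trivial provider for exercising the hook plumbing; always 1.0."""
    return 1.0
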