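"""Target-gene set construction.

A TF's target genes are the union of (i) genes with documented regulation
evidence and (ii) genes whose promoters carry a posterior-filtered binding
site of the TF.  When a TF has several passing sites assigned to the same
gene, only the single most confident site is kept for downstream occupancy
calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .data import DataError, RegulationTable, TFBSRecord, canonical_pair

DEFAULT_POSTERIOR_THRESHOLD = 0.3
DEFAULT_TOTAL_GENES = 6576

BestSiteIndex = dict[tuple[str, str], TFBSRecord]


@dataclass(frozen=True)
class TargetGeneSets:
    """Mapping TF -> target-gene set, plus the gene-universe size."""

    targets: Mapping[str, frozenset[str]]
    total_genes: int

    def __post_init__(self):
        universe = set()
        for genes in self.targets.values():
            universe |= genes
        if self.total_genes < len(universe):
            raise DataError(
                f"total_genes={self.total_genes} smaller than the "
                f"{len(universe)} distinct genes observed"
            )

    @property
    def tfs(self) -> list[str]:
        return sorted(self.targets)

    def __getitem__(self, tf: str) -> frozenset[str]:
        return self.targets[tf]


def filter_tfbs(
    sites: Iterable[TFBSRecord], posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD
) -> list[TFBSRecord]:
    """Keep sites whose posterior is >= the threshold (inclusive)."""
    if not 0.0 <= posterior_threshold <= 1.0:
        raise DataError(f"posterior threshold {posterior_threshold} outside [0, 1]")
    return [s for s in sites if s.posterior >= posterior_threshold]


def _site_rank(site: TFBSRecord) -> tuple:
    # highest posterior wins; ties: smallest start, then chromosome name,
    # then remaining fields for full determinism
    return (-site.posterior, site.start, site.chrom, site.end, site.strand)


def build_best_site_index(sites: Sequence[TFBSRecord]) -> BestSiteIndex:
    """Select one maximal-posterior site per (TF, gene), deterministically."""
    best: BestSiteIndex = {}
    for site in sites:
        key = (site.tf, site.gene)
        cur = best.get(key)
        if cur is None or _site_rank(site) < _site_rank(cur):
            best[key] = site
    return best


def define_targets(
    regulation: RegulationTable,
    best_sites: BestSiteIndex,
    total_genes: int = DEFAULT_TOTAL_GENES,
) -> TargetGeneSets:
    """Union documented-regulation and binding-site evidence per TF.

    TFs seen in either source are retained even if their final set is empty.
    """
    targets: dict[str, set[str]] = {}
    for tf, gene in regulation.records:
        targets.setdefault(tf, set()).add(gene)
    for (tf, gene) in best_sites:
        targets.setdefault(tf, set()).add(gene)
    frozen = {tf: frozenset(genes) for tf, genes in targets.items()}
    return TargetGeneSets(targets=frozen, total_genes=total_genes)


def enumerate_pairs(tfs) -> list[tuple[str, str]]:
    """All k(k-1)/2 unordered TF pairs, canonically ordered, sorted.

    Accepts a :class:`TargetGeneSets` or any iterable of TF identifiers.
    """
    if isinstance(tfs, TargetGeneSets):
        names = tfs.tfs
    else:
        from .data import normalize_id

        names = sorted({normalize_id(t) for t in tfs})
    if len(names) < 2:
        raise DataError(f"need at least 2 TFs to enumerate pairs, got {len(names)}")
    pairs = [
        canonical_pair(names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    return sorted(pairs)
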