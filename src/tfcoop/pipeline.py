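"""File-level orchestration: read inputs, build targets, score pairs."""

from __future__ import annotations

from .data import NucleosomeTrack, PairResult, read_nucleosome_track, read_regulation, read_tfbs
from .targets import (
    DEFAULT_POSTERIOR_THRESHOLD,
    DEFAULT_TOTAL_GENES,
    BestSiteIndex,
    TargetGeneSets,
    build_best_site_index,
    define_targets,
    filter_tfbs,
)
from .scoring import score_all_pairs


def build_inputs(
    regulation_path,
    tfbs_path,
    nucleosome_path,
    *,
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    total_genes: int = DEFAULT_TOTAL_GENES,
) -> tuple[TargetGeneSets, BestSiteIndex, NucleosomeTrack]:
    regulation = read_regulation(regulation_path)
    sites = filter_tfbs(read_tfbs(tfbs_path), posterior_threshold)
    best_sites = build_best_site_index(sites)
    track = read_nucleosome_track(nucleosome_path)
    targets = define_targets(regulation, best_sites, total_genes)
    return targets, best_sites, track


def score_files(
    regulation_path,
    tfbs_path,
    nucleosome_path,
    *,
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    total_genes: int = DEFAULT_TOTAL_GENES,
    disable_nucleosome: bool = False,
) -> list[PairResult]:
    targets, best_sites, track = build_inputs(
        regulation_path,
        tfbs_path,
        nucleosome_path,
        posterior_threshold=posterior_threshold,
        total_genes=total_genes,
    )
    return score_all_pairs(
        targets, best_sites, track, disable_nucleosome=disable_nucleosome
    )
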