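"""Synthetic regulatory datasets with planted cooperative TF pairs.

Each gene owns a disjoint promoter window on one synthetic chromosome and
each TF owns a fixed slot inside every promoter, so binding sites never
collide.  Target relationships are Bernoulli draws per (TF, gene); planted
pairs additionally receive a block of shared targets sized so the shared
fraction of their target sets matches the configured value.  Nucleosome
occupancy is sampled per site and materialized as occupied intervals that
cover exactly the occupied sites, which makes the downstream contingency
cells directly controllable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import data
from .data import DataError, PPINetwork, RegulationTable, TFBSRecord

SITE_WIDTH = 10
CHROM = "chrS"


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 600
    n_tfs: int = 20
    n_planted_pairs: int = 3
    background_target_rate: float = 0.05
    planted_shared_fraction: float = 0.6
    promoter_length: int = 1000
    background_occupancy_rate: float = 0.7
    planted_codepletion_rate: float = 0.8
    posterior_min: float = 0.3
    posterior_max: float = 1.0
    tfbs_dropout: float = 0.0  # fraction of targets with regulation-only evidence
    n_noise_ppi_edges: int = 10
    seed: int = 0

    def __post_init__(self):
        rates = {
            "background_target_rate": self.background_target_rate,
            "planted_shared_fraction": self.planted_shared_fraction,
            "background_occupancy_rate": self.background_occupancy_rate,
            "planted_codepletion_rate": self.planted_codepletion_rate,
            "tfbs_dropout": self.tfbs_dropout,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise DataError(f"{name}={r} outside [0, 1]")
        if not 0.0 <= self.posterior_min <= self.posterior_max <= 1.0:
            raise DataError("posterior bounds must satisfy 0 <= min <= max <= 1")
        if 2 * self.n_planted_pairs > self.n_tfs:
            raise DataError("n_planted_pairs exceeds n_tfs / 2")
        if self.n_tfs * SITE_WIDTH > self.promoter_length:
            raise DataError(
                f"promoter_length={self.promoter_length} too short for "
                f"{self.n_tfs} non-overlapping {SITE_WIDTH}-bp sites"
            )

    def null(self) -> "SyntheticConfig":
        """Variant with all planted effects disabled.

        No forced target sharing, and planted-pair sites fall back to the
        background occupancy process.
        """
        return replace(
            self,
            planted_shared_fraction=0.0,
            planted_codepletion_rate=0.0,
        )


@dataclass(frozen=True)
class GroundTruth:
    planted_pairs: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class SyntheticDataset:
    regulation_path: Path
    tfbs_path: Path
    nucleosome_path: Path
    ppi_path: Path
    truth: GroundTruth
    config: SyntheticConfig = field(repr=False, default=None)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _tf_name(i: int) -> str:
    return f"TF{i:02d}"


def generate(config: SyntheticConfig, out_dir) -> SyntheticDataset:
    """Write regulation/TFBS/nucleosome/PPI files; fully seed-reproducible."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes = [_gene_name(i) for i in range(config.n_genes)]
    tfs = [_tf_name(i + 1) for i in range(config.n_tfs)]
    planted = [
        (tfs[2 * i], tfs[2 * i + 1]) for i in range(config.n_planted_pairs)
    ]

    # background targets, drawn TF by TF in fixed order
    targets: dict[str, set[str]] = {}
    for tf in tfs:
        mask = rng.random(config.n_genes) < config.background_target_rate
        targets[tf] = {genes[i] for i in np.flatnonzero(mask)}

    # force shared targets for planted pairs: s / (b + s) = shared fraction
    shared_by_pair: dict[tuple[str, str], set[str]] = {}
    for tf1, tf2 in planted:
        f = config.planted_shared_fraction
        if f >= 1.0:
            raise DataError("planted_shared_fraction must be < 1")
        b = 0.5 * (len(targets[tf1]) + len(targets[tf2]))
        s = int(round(f * b / (1.0 - f))) if f > 0 else 0
        shared = set(
            genes[i] for i in rng.choice(config.n_genes, size=s, replace=False)
        ) if s else set()
        targets[tf1] |= shared
        targets[tf2] |= shared
        shared_by_pair[(tf1, tf2)] = shared

    # per-site occupancy states; planted shared sites get joint co-depletion
    occupied: dict[tuple[str, str], bool] = {}
    for tf in tfs:
        for gene in sorted(targets[tf]):
            occupied[(tf, gene)] = bool(rng.random() < config.background_occupancy_rate)
    for (tf1, tf2), shared in shared_by_pair.items():
        for gene in sorted(shared):
            if rng.random() < config.planted_codepletion_rate:
                occupied[(tf1, gene)] = False
                occupied[(tf2, gene)] = False
            else:
                occupied[(tf1, gene)] = bool(
                    rng.random() < config.background_occupancy_rate
                )
                occupied[(tf2, gene)] = bool(
                    rng.random() < config.background_occupancy_rate
                )

    # emit one site per (tf, target) inside the gene's promoter slot
    gene_index = {g: i for i, g in enumerate(genes)}
    tf_index = {t: i for i, t in enumerate(tfs)}
    sites: list[TFBSRecord] = []
    dropped: set[tuple[str, str]] = set()
    for tf in tfs:
        for gene in sorted(targets[tf]):
            if config.tfbs_dropout and rng.random() < config.tfbs_dropout:
                dropped.add((tf, gene))
                continue
            start = (
                gene_index[gene] * config.promoter_length
                + tf_index[tf] * SITE_WIDTH
            )
            posterior = float(
                rng.uniform(config.posterior_min, config.posterior_max)
            )
            sites.append(
                TFBSRecord(
                    tf=tf, chrom=CHROM, start=start, end=start + SITE_WIDTH,
                    strand="+", posterior=round(posterior, 6), gene=gene,
                )
            )
    sites.sort(key=lambda s: (s.start, s.tf))

    nucleosome = sorted(
        (CHROM, s.start, s.end) for s in sites if occupied[(s.tf, s.gene)]
    )

    regulation = RegulationTable(
        records=frozenset(
            (tf, gene) for tf in tfs for gene in targets[tf]
        )
    )

    edges = {tuple(sorted(p)) for p in planted}
    n_extra = 0
    while n_extra < config.n_noise_ppi_edges:
        i, j = rng.choice(config.n_tfs, size=2, replace=False)
        edge = tuple(sorted((tfs[i], tfs[j])))
        if edge not in edges:
            edges.add(edge)
            n_extra += 1
    ppi = PPINetwork(edges=frozenset(edges))

    paths = SyntheticDataset(
        regulation_path=out_dir / "regulation.tsv",
        tfbs_path=out_dir / "tfbs.bed",
        nucleosome_path=out_dir / "nucleosome.bed",
        ppi_path=out_dir / "ppi.tsv",
        truth=GroundTruth(
            planted_pairs=frozenset(tuple(sorted(p)) for p in planted)
        ),
        config=config,
    )
    data.write_regulation(regulation, paths.regulation_path)
    data.write_tfbs(sites, paths.tfbs_path)
    data.write_nucleosome_track(nucleosome, paths.nucleosome_path)
    data.write_ppi(ppi, paths.ppi_path)
    with open(out_dir / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        for tf1, tf2 in sorted(paths.truth.planted_pairs):
            fh.write(f"{tf1}\t{tf2}\n")
    with open(out_dir / "config.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def recovery_check(results, truth: GroundTruth, top_k: int) -> float:
    """Fraction of planted pairs found in the top_k of a ranked result list."""
    if not truth.planted_pairs:
        return 0.0
    top = {r.pair for r in results[:top_k]}
    hits = sum(1 for p in truth.planted_pairs if tuple(sorted(p)) in top)
    return hits / len(truth.planted_pairs)
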