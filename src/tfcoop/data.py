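"""Domain types and tabular I/O.

All genomic intervals are 0-based half-open (BED convention).  TF and gene
identifiers are matched case-insensitively and stored upper-cased; the
upstream databases mix cases freely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


class ParseError(DataError):
    """Malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def normalize_id(name: str) -> str:
    """Upper-case and strip an identifier; empty identifiers are invalid."""
    out = name.strip().upper()
    if not out:
        raise DataError("empty identifier")
    return out


def canonical_pair(x: str, y: str) -> tuple[str, str]:
    """Order-independent representation of an unordered identifier pair."""
    a, b = normalize_id(x), normalize_id(y)
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulationTable:
    """Documented TF -> gene regulation evidence, deduplicated."""

    records: frozenset[tuple[str, str]]

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.records}

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.records}

    def targets_of(self, tf: str) -> set[str]:
        tf = normalize_id(tf)
        return {g for t, g in self.records if t == tf}


@dataclass(frozen=True)
class TFBSRecord:
    """A located binding site with a posterior probability and gene assignment."""

    tf: str
    chrom: str
    start: int
    end: int
    strand: str
    posterior: float
    gene: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval [{self.start}, {self.end}) for {self.tf}"
            )
        if not (0.0 <= self.posterior <= 1.0):
            raise DataError(f"posterior {self.posterior} outside [0, 1]")
        if self.strand not in VALID_STRANDS:
            raise DataError(f"invalid strand {self.strand!r}")
        if not self.gene:
            raise DataError("TFBS record lacks a gene assignment")


class NucleosomeTrack:
    """Occupied genomic intervals, queryable for overlap per chromosome.

    Intervals are stored sorted by start with a running maximum of ends, so
    an overlap query is two binary searches.  Chromosomes absent from the
    track report no overlap.
    """

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._n = 0
        for chrom, ivs in intervals.items():
            pairs = sorted(set((int(s), int(e)) for s, e in ivs))
            for s, e in pairs:
                if s >= e:
                    raise DataError(f"invalid interval [{s}, {e}) on {chrom}")
            if not pairs:
                continue
            starts = np.array([s for s, _ in pairs], dtype=np.int64)
            ends = np.array([e for _, e in pairs], dtype=np.int64)
            self._index[chrom] = (starts, np.maximum.accumulate(ends))
            self._n += len(pairs)

    def __len__(self) -> int:
        return self._n

    @property
    def chroms(self) -> set[str]:
        return set(self._index)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any occupied interval on chrom."""
        if start >= end:
            raise DataError(f"invalid query interval [{start}, {end})")
        entry = self._index.get(chrom)
        if entry is None:
            return False
        starts, max_ends = entry
        # candidates have interval start < query end
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and int(max_ends[i - 1]) > start

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._index):
            starts, _ = self._index[chrom]
            # recover true ends from the running maximum is impossible, so
            # keep the raw list too
            for s, e in zip(starts, self._raw[chrom]):
                yield chrom, int(s), int(e)

    # raw ends kept only for round-trip export
    @property
    def _raw(self) -> dict[str, list[int]]:
        raw = getattr(self, "_raw_ends", None)
        if raw is None:
            raise AttributeError("raw ends unavailable")
        return raw

    @classmethod
    def from_intervals(cls, triples: Iterable[tuple[str, int, int]]) -> "NucleosomeTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in triples:
            by_chrom.setdefault(chrom, []).append((s, e))
        track = cls(by_chrom)
        track._raw_ends = {
            chrom: [e for _, e in sorted(set(ivs))] for chrom, ivs in by_chrom.items()
        }
        return track


@dataclass(frozen=True)
class PPINetwork:
    """Undirected physical protein-protein interaction network."""

    edges: frozenset[tuple[str, str]]

    def partners(self, protein: str) -> set[str]:
        """Interaction partners of ``protein``, excluding itself."""
        p = normalize_id(protein)
        out: set[str] = set()
        for x, y in self.edges:
            if x == p and y != p:
                out.add(y)
            elif y == p and x != p:
                out.add(x)
        return out

    @property
    def proteins(self) -> set[str]:
        return {p for edge in self.edges for p in edge}


@dataclass(frozen=True)
class PairAnnotationRow:
    """One row of the packaged predicted-pair annotation table."""

    rank: int
    tf1: str
    tf2: str
    method_citations: tuple[str, ...]
    has_ppi: bool  # True = documented PPI; False = no/unknown
    mips_categories: tuple[str, ...]

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.tf1, self.tf2)


@dataclass(frozen=True)
class BenchmarkSet:
    """Unordered known cooperative TF pairs with complex annotations."""

    pairs: frozenset[tuple[str, str]]
    complexes: Mapping[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return canonical_pair(*pair) in self.pairs

    @property
    def tfs(self) -> set[str]:
        return {tf for pair in self.pairs for tf in pair}


@dataclass(frozen=True)
class PairResult:
    """Per-TF-pair statistics and cooperativity score.

    p-values are carried both as floats (which may underflow to 0.0) and as
    log10 values, which are always finite; the score is computed from the
    log-space values.
    """

    tf1: str
    tf2: str
    n1: int
    n2: int
    m: int
    p_overlap: float
    log10_p_overlap: float
    a: int
    b: int
    c: int
    d: int
    p_nu: float
    log10_p_nu: float
    score: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.tf1, self.tf2)

    @property
    def set_a_size(self) -> int:
        return self.a + self.b + self.c + self.d


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _iter_data_lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_regulation(path, *, header: bool = False) -> RegulationTable:
    """Read a two-column TSV of documented TF -> gene regulation."""
    records: set[tuple[str, str]] = set()
    n_read = 0
    for lineno, fields in _iter_data_lines(path):
        if header and n_read == 0 and lineno == 1:
            continue
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected >=2 columns, got {len(fields)}")
        try:
            rec = (normalize_id(fields[0]), normalize_id(fields[1]))
        except DataError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        n_read += 1
        records.add(rec)
    logger.info(
        "read %d regulation records from %s (%d duplicates dropped)",
        n_read, path, n_read - len(records),
    )
    return RegulationTable(records=frozenset(records))


def read_tfbs(path) -> list[TFBSRecord]:
    """Read binding sites from BED6+1: chrom, start, end, TF, posterior, strand, gene."""
    records: list[TFBSRecord] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 7:
            raise ParseError(path, lineno, f"expected 7 columns, got {len(fields)}")
        try:
            records.append(
                TFBSRecord(
                    tf=normalize_id(fields[3]),
                    chrom=fields[0].strip(),
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5].strip(),
                    posterior=float(fields[4]),
                    gene=normalize_id(fields[6]),
                )
            )
        except (DataError, ValueError) as exc:
            raise ParseError(path, lineno, str(exc)) from exc
    logger.info("read %d TFBS records from %s", len(records), path)
    return records


def read_nucleosome_track(path) -> NucleosomeTrack:
    """Read occupied intervals from a BED3 file."""
    triples: list[tuple[str, int, int]] = []
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected 3 columns, got {len(fields)}")
        try:
            chrom, start, end = fields[0].strip(), int(fields[1]), int(fields[2])
            if start >= end:
                raise DataError(f"invalid interval [{start}, {end})")
        except (DataError, ValueError) as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        triples.append((chrom, start, end))
    return NucleosomeTrack.from_intervals(triples)


def read_ppi(path) -> PPINetwork:
    """Read an undirected edge list from a two-column TSV."""
    edges: set[tuple[str, str]] = set()
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        try:
            x, y = normalize_id(fields[0]), normalize_id(fields[1])
        except DataError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        edges.add((x, y) if x <= y else (y, x))
    return PPINetwork(edges=frozenset(edges))


def read_pairs(path) -> BenchmarkSet:
    """Read unordered TF pairs (>=2 columns; extra columns are annotations)."""
    pairs: set[tuple[str, str]] = set()
    complexes: dict[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for lineno, fields in _iter_data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected >=2 columns, got {len(fields)}")
        try:
            pair = canonical_pair(fields[0], fields[1])
        except DataError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        if pair[0] == pair[1]:
            raise ParseError(path, lineno, f"self-pair {pair[0]}")
        pairs.add(pair)
        if len(fields) >= 4:
            ids = tuple(t for t in fields[2].split(",") if t)
            names = tuple(t for t in fields[3].split("|") if t)
            complexes[pair] = (ids, names)
    return BenchmarkSet(pairs=frozenset(pairs), complexes=complexes)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_regulation(table: RegulationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tf, gene in sorted(table.records):
            fh.write(f"{tf}\t{gene}\n")


def write_tfbs(records: Sequence[TFBSRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.tf}\t{r.posterior:.6g}"
                f"\t{r.strand}\t{r.gene}\n"
            )


def write_nucleosome_track(triples: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end in triples:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_ppi(network: PPINetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for x, y in sorted(network.edges):
            fh.write(f"{x}\t{y}\n")


PAIR_RESULT_COLUMNS = (
    "tf1", "tf2", "n1", "n2", "m", "p_overlap", "log10_p_overlap",
    "a", "b", "c", "d", "p_nu", "log10_p_nu", "score",
)


def write_pair_results(results: Sequence[PairResult], path) -> None:
    """Write scored pairs to TSV, one row per pair, in the given order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PAIR_RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.tf1}\t{r.tf2}\t{r.n1}\t{r.n2}\t{r.m}"
                f"\t{r.p_overlap:.6e}\t{r.log10_p_overlap:.10g}"
                f"\t{r.a}\t{r.b}\t{r.c}\t{r.d}"
                f"\t{r.p_nu:.6e}\t{r.log10_p_nu:.10g}\t{r.score:.10g}\n"
            )


def read_pair_results(path) -> list[PairResult]:
    results: list[PairResult] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PAIR_RESULT_COLUMNS:
            raise ParseError(path, 1, f"unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(PAIR_RESULT_COLUMNS):
                raise ParseError(path, lineno, f"expected {len(PAIR_RESULT_COLUMNS)} columns")
            results.append(
                PairResult(
                    tf1=f[0], tf2=f[1], n1=int(f[2]), n2=int(f[3]), m=int(f[4]),
                    p_overlap=float(f[5]), log10_p_overlap=float(f[6]),
                    a=int(f[7]), b=int(f[8]), c=int(f[9]), d=int(f[10]),
                    p_nu=float(f[11]), log10_p_nu=float(f[12]), score=float(f[13]),
                )
            )
    return results


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str) -> Path:
    ref = resources.files("tfcoop").joinpath("fixtures", name)
    path = Path(str(ref))
    if not path.exists():
        raise FileNotFoundError(f"packaged fixture {name!r} is missing")
    return path


def load_table1_fixture() -> list[PairAnnotationRow]:
    """Load the packaged 27-row predicted-pair annotation table."""
    rows: list[PairAnnotationRow] = []
    path = _fixture_path("predicted_pairs_annotation.tsv")
    for lineno, fields in _iter_data_lines(path):
        if fields[0] == "rank":
            continue
        if not 3 <= len(fields) <= 6:
            raise ParseError(path, lineno, f"expected 3-6 columns, got {len(fields)}")
        fields = fields + [""] * (6 - len(fields))  # trailing empties may be omitted
        rank, tf1, tf2, cites, ppi, mips = fields
        rows.append(
            PairAnnotationRow(
                rank=int(rank),
                tf1=normalize_id(tf1),
                tf2=normalize_id(tf2),
                method_citations=tuple(t for t in cites.split(",") if t),
                has_ppi=(ppi.strip().upper() == "Y"),
                mips_categories=tuple(t.strip() for t in mips.split(";") if t.strip()),
            )
        )
    ranks = sorted(r.rank for r in rows)
    if ranks != list(range(1, len(rows) + 1)):
        raise DataError("annotation fixture ranks are not 1..n each exactly once")
    return rows


def load_benchmark_fixture() -> BenchmarkSet:
    """Load the packaged benchmark of known cooperative TF pairs."""
    return read_pairs(_fixture_path("benchmark_pairs.tsv"))
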