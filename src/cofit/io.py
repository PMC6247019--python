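"""Core domain types and file I/O.

External conventions, used at every file boundary:

* genome sequences: FASTA;
* gene annotation: GFF3, coordinates 1-based inclusive;
* tabular data (insertion tables, count matrices, result reports): tab-separated
  values with a header row, UTF-8, ``.`` decimal separator;
* optional per-TA-site count tracks: text ``variableStep`` wig.

Internally arithmetic is 0-based half-open; every public type carries 1-based
inclusive coordinates so files round-trip exactly.  A TA site is identified by
the 1-based position of its T (TA is its own reverse complement, so a single
strandless coordinate suffices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "Genome",
    "GeneAnnotation",
    "InsertObservation",
    "OutgrowthParams",
    "GeneFitnessSummary",
    "ConditionalFitnessResult",
    "StrainComparisonResult",
    "ExpressionCounts",
    "SyntheticTruth",
    "CATEGORIES",
    "read_genome",
    "write_genome",
    "read_annotation",
    "write_annotation",
    "read_insertion_table",
    "write_insertion_table",
    "read_insertion_wig",
    "write_insertion_wig",
    "read_expression_counts",
    "write_expression_counts",
    "read_truth",
    "write_truth",
]

#: Gene categories from the five-way essentiality/benefit classification.
CATEGORIES = ("detrimental", "beneficial", "neutral", "lethal", "insufficient")

_NUCLEOTIDES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


@dataclass(frozen=True)
class Genome:
    """A single replicon: an identifier and an upper-case DNA sequence.

    ``N`` is tolerated (ambiguous base); TA-site enumeration never reports a
    window containing ``N`` because such a window is not ``TA``.
    """

    sequence_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"genome record {self.sequence_id!r} is empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _NUCLEOTIDES
        if bad:
            raise FormatError(
                f"genome record {self.sequence_id!r} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene, 1-based inclusive coordinates on a named replicon."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    seqid: str = "genome"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class InsertObservation:
    """Read counts for one transposon insert in one library.

    ``site`` is the 1-based position of the T of the TA dinucleotide.
    ``count_tf`` is ``None`` when the final time point has not been sequenced
    (a t0-only library).  Counts may be non-integral only for observations
    produced by the noiseless simulation mode; file readers enforce integers.
    An insert is eligible for fitness estimation only when ``count_t0 > 0``.
    """

    site: int
    count_t0: float
    count_tf: Optional[float] = None
    library_id: str = "lib1"

    def __post_init__(self) -> None:
        if self.site < 1:
            raise FormatError(f"insert site {self.site} is not a 1-based position")
        if self.count_t0 < 0 or (self.count_tf is not None and self.count_tf < 0):
            raise FormatError(f"negative read count at site {self.site}")

    @property
    def eligible(self) -> bool:
        """Whether the insert is admitted to fitness estimation."""
        return self.count_t0 > 0


@dataclass(frozen=True)
class OutgrowthParams:
    """Selective-outgrowth parameters.

    ``generations`` is the number of population doublings of a neutral clone;
    ``expansion_factor`` (d) is the fold-expansion of the whole population over
    the outgrowth and defaults to ``2**generations``.  A simulation reports the
    realized d alongside its counts, and that value should be preferred.
    """

    generations: float
    expansion_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError("generations must be > 0")
        if self.d <= 1:
            raise ValueError("expansion factor d must be > 1")

    @property
    def d(self) -> float:
        if self.expansion_factor is not None:
            return self.expansion_factor
        return 2.0 ** self.generations


@dataclass
class GeneFitnessSummary:
    """Per-gene aggregate of insert fitness values plus the category call."""

    gene_id: str
    insert_fitness_values: list = field(default_factory=list)
    mean_w: float = math.nan
    sd_w: float = math.nan
    n_inserts: int = 0
    n_floored: int = 0
    category: Optional[str] = None


@dataclass
class ConditionalFitnessResult:
    """Gene-level fitness difference between two arms of one experiment."""

    gene_id: str
    delta_w: float
    t_statistic: float
    p_value: float
    significant: bool
    flag: str = "ok"


@dataclass
class StrainComparisonResult:
    """Background-corrected fitness comparison of one gene between strains."""

    gene_id: str
    delta_wt: float
    delta_mut: float
    t_statistic: float
    p_value: float
    significant: bool
    wt_significant: bool
    mut_significant: bool
    degradation_dependent: bool
    flag: str = "ok"


class ExpressionCounts:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with one column per sample.
    metadata
        DataFrame indexed by sample with columns ``condition`` and
        ``replicate``; rows must match the count columns.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame) -> None:
        if (counts.to_numpy() < 0).any():
            raise FormatError("expression counts contain negative entries")
        if list(counts.columns) != list(metadata.index):
            raise FormatError("count columns and metadata rows do not match")
        if not {"condition", "replicate"}.issubset(metadata.columns):
            raise FormatError("metadata requires 'condition' and 'replicate' columns")
        self.counts = counts
        self.metadata = metadata

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.metadata["condition"]))

    def samples_for(self, condition: str) -> list:
        return list(self.metadata.index[self.metadata["condition"] == condition])

    def smallest_group_size(self) -> int:
        return int(self.metadata["condition"].value_counts().min())


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generators, used only for scoring recovery.

    ``fitness``: DataFrame indexed by gene_id with at least ``true_w`` (neutral
    genes carry exactly 1.0), ``essential`` (essential genes receive zero
    inserts), and ``true_category``; additional per-arm columns (for example
    ``true_w_stress``) describe conditional effects.  ``expression``: DataFrame
    indexed by gene_id, one column of true log2 fold change per condition.
    """

    fitness: Optional[pd.DataFrame] = None
    expression: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path) -> list[Genome]:
    """Read a FASTA file; every record becomes one :class:`Genome`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return [Genome(rec.id, str(rec.seq)) for rec in records]


def write_genome(genomes: Sequence[Genome], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.sequence_id, description="")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_annotation(path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file (1-based inclusive per the standard).

    Only features of ``feature_type`` are retained; the ``ID`` attribute
    becomes the gene_id.  Duplicate IDs and inverted intervals are format
    errors.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneAnnotation] = []
    seen: dict[str, int] = {}
    for feat in db.all_features(featuretype=feature_type):
        ids = feat.attributes.get("ID", [feat.id])
        gene_id = ids[0]
        seen[gene_id] = seen.get(gene_id, 0) + 1
        if feat.start > feat.end:
            raise FormatError(
                f"gene {gene_id!r}: start {feat.start} > end {feat.end}"
            )
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneAnnotation(gene_id, feat.start, feat.end, strand, seqid=feat.seqid)
        )
    duplicates = sorted(g for g, n in seen.items() if n > 1)
    if duplicates:
        raise FormatError(f"duplicate gene IDs in {path}: {duplicates}")
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path, source: str = "cofit") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seqid}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Insertion tables (TSV and wig tracks)

_INSERT_COLUMNS = ["site", "count_t0", "count_tf", "library_id"]


def _check_count(value, what: str, site) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if value < 0:
        raise FormatError(f"negative {what} at site {site}")
    if float(value) != int(value):
        raise FormatError(f"non-integer {what} at site {site}: {value}")
    return float(int(value))


def read_insertion_table(path) -> list[InsertObservation]:
    """Read a per-site insertion count TSV.

    Columns: site, count_t0, count_tf, library_id.  ``count_tf`` may be ``NA``
    for t0-only libraries.  Rows with ``count_t0 == 0`` are retained but
    flagged ineligible for fitness estimation.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _INSERT_COLUMNS if c not in df.columns and c != "count_tf"]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    has_tf = "count_tf" in df.columns
    out = []
    for row in df.itertuples(index=False):
        t0 = _check_count(row.count_t0, "count_t0", row.site)
        if t0 is None:
            raise FormatError(f"missing count_t0 at site {row.site}")
        tf = _check_count(row.count_tf, "count_tf", row.site) if has_tf else None
        out.append(InsertObservation(int(row.site), t0, tf, str(row.library_id)))
    return out


def _fmt_count(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


def write_insertion_table(observations: Iterable[InsertObservation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_INSERT_COLUMNS) + "\n")
        for obs in observations:
            fh.write(
                f"{obs.site}\t{_fmt_count(obs.count_t0)}\t{_fmt_count(obs.count_tf)}\t"
                f"{obs.library_id}\n"
            )


def write_insertion_wig(
    observations: Sequence[InsertObservation], t0_path, tf_path=None, chrom: str = "genome"
) -> None:
    """Write per-TA-site count tracks as text variableStep wig (one line per site)."""

    def _write(path, getter):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"variableStep chrom={chrom}\n")
            for obs in sorted(observations, key=lambda o: o.site):
                fh.write(f"{obs.site}\t{_fmt_count(getter(obs))}\n")

    _write(t0_path, lambda o: o.count_t0)
    if tf_path is not None:
        _write(tf_path, lambda o: o.count_tf)


def _read_wig_track(path) -> dict[int, float]:
    track: dict[int, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("variableStep", "fixedStep", "track")):
                continue
            pos_str, val_str = line.split()
            value = float(val_str)
            track[int(pos_str)] = value
    return track


def read_insertion_wig(t0_path, tf_path=None, library_id: str = "lib1") -> list[InsertObservation]:
    """Read a wig track pair (t0 required, tf optional) into observations."""
    t0 = _read_wig_track(t0_path)
    tf = _read_wig_track(tf_path) if tf_path is not None else None
    if tf is not None and set(tf) != set(t0):
        raise FormatError("t0 and tf wig tracks cover different sites")
    out = []
    for site in sorted(t0):
        c0 = _check_count(t0[site], "count_t0", site)
        ctf = _check_count(tf[site], "count_tf", site) if tf is not None else None
        out.append(InsertObservation(site, c0, ctf, library_id))
    return out


# ---------------------------------------------------------------------------
# Expression matrices and truth tables


def read_expression_counts(counts_path, metadata_path) -> ExpressionCounts:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if not all(np.issubdtype(dt, np.number) for dt in counts.dtypes):
        raise FormatError(f"{counts_path}: non-numeric count entries")
    arr = counts.to_numpy()
    if (arr != np.floor(arr)).any():
        raise FormatError(f"{counts_path}: non-integer count entries")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return ExpressionCounts(counts.astype(np.int64), metadata)


def write_expression_counts(ec: ExpressionCounts, counts_path, metadata_path) -> None:
    ec.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    ec.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_truth(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "true_w" in df.columns:
        if "essential" in df.columns:
            df["essential"] = df["essential"].astype(bool)
        return SyntheticTruth(fitness=df)
    return SyntheticTruth(expression=df)


def write_truth(truth: SyntheticTruth, path, which: str = "fitness") -> None:
    table = truth.fitness if which == "fitness" else truth.expression
    if table is None:
        raise ValueError(f"truth has no {which} table")
    table.to_csv(path, sep="\t", index_label="gene_id")
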