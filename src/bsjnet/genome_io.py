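"""Genome FASTA / BED parsing and back-splice-junction flank extraction.

A circRNA is formed when a downstream splice donor joins an upstream splice
acceptor (back-splicing).  The discriminative signal for classifying a
candidate as circRNA vs lncRNA lives in the sequence immediately around the
two back-splice sites, so the feature sequence for a record is built by
taking a fixed-width window around each of the interval's two endpoints and
concatenating them: 50 nt per side per site by default, i.e. a 100-nt window
centred on each site, merged into a single 200-nt feature sequence.

Coordinates follow the standard BED convention: 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LABEL_POSITIVE = "circRNA"
LABEL_NEGATIVE = "lncRNA"


class ExtractionError(ValueError):
    """A flank window falls outside its chromosome."""


@dataclass
class Genome:
    """Chromosome name -> uppercase sequence over {A,C,G,T,N}."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains letters outside A/C/G/T/N: {sorted(bad)}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def __getitem__(self, chrom: str) -> str:
        return self.records[chrom]


@dataclass(frozen=True)
class GenomicInterval:
    """One labeled BED record (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    label: str = LABEL_POSITIVE

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end} for {self.name or self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.label not in (LABEL_POSITIVE, LABEL_NEGATIVE):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class FeatureSequence:
    """Merged junction feature sequence with provenance.

    ``sequence`` is the concatenation of the acceptor-side window (centred on
    the interval start) and the donor-side window (centred on the interval
    end), in transcript orientation; length is always ``4 * flank_len``.
    """

    sequence: str
    source: GenomicInterval
    flank_len: int = 50

    def __post_init__(self) -> None:
        if len(self.sequence) != 4 * self.flank_len:
            raise ValueError(
                f"feature sequence length {len(self.sequence)} != 4*flank_len={4 * self.flank_len}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Feature sequences with binary labels and an optional split assignment."""

    examples: list[FeatureSequence]
    labels: np.ndarray  # int {0,1}, 1 = circRNA
    split: np.ndarray | None = None  # "train" / "validation" / "test" per example
    n_skipped: int = 0
    n_deduplicated: int = 0

    def __len__(self) -> int:
        return len(self.examples)

    def subset(self, which: str) -> "LabeledDataset":
        if self.split is None:
            raise ValueError("dataset has no split assignment; call split_dataset first")
        mask = self.split == which
        return LabeledDataset(
            examples=[e for e, m in zip(self.examples, mask) if m],
            labels=self.labels[mask],
        )

    @property
    def sequences(self) -> list[str]:
        return [e.sequence for e in self.examples]


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T (RNA input), and any other non-ACGT letter to N."""
    seq = seq.upper().replace("U", "T")
    return "".join(c if c in "ACGT" else "N" for c in seq)


def read_fasta(path) -> Genome:
    """Read a genome FASTA into memory.

    Headers are truncated at the first whitespace; sequences are normalized
    via :func:`normalize_sequence`.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id  # SeqIO already splits the header at whitespace
        if name in records:
            raise ValueError(f"duplicate chromosome name {name!r}")
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"empty record {name!r}")
        records[name] = seq
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return Genome(records)


def read_bed(path, label: str) -> list[GenomicInterval]:
    """Read a 3-6 column BED file, attaching `label` to every record.

    Column 4 (name) is auto-generated when absent; column 6 (strand)
    defaults to '+'.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{i + 1}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{i + 1}: non-integer coordinates") from exc
            name = cols[3] if len(cols) > 3 and cols[3] else f"{label}_{i + 1}"
            strand = cols[5] if len(cols) > 5 and cols[5] else "+"
            intervals.append(
                GenomicInterval(
                    chrom=cols[0], start=start, end=end, strand=strand, name=name, label=label
                )
            )
    return intervals


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def reverse_complement(seq: str) -> str:
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"illegal characters for reverse complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_junction_flanks(
    interval: GenomicInterval,
    genome: Genome,
    flank_len: int = 50,
    *,
    pad: bool = False,
) -> FeatureSequence:
    """Extract the merged junction feature sequence for one interval.

    Plus strand: the ``2*flank_len`` window centred on ``start`` (acceptor
    side) followed by the window centred on ``end`` (donor side).  Minus
    strand: reverse complement of the merged plus-strand product, which
    places the window around the genomic end (the minus-strand acceptor)
    first, so the acceptor side always comes first in transcript
    orientation.

    Windows that fall outside the chromosome raise :class:`ExtractionError`
    (a skippable failure) unless ``pad`` is set, in which case the missing
    positions are filled with N.
    """
    if interval.chrom not in genome:
        raise ExtractionError(f"chromosome {interval.chrom!r} not in genome")
    chrom_seq = genome[interval.chrom]

    def window(center: int) -> str:
        lo, hi = center - flank_len, center + flank_len
        if lo < 0 or hi > len(chrom_seq):
            if not pad:
                raise ExtractionError(
                    f"window [{lo},{hi}) around position {center} outside chromosome "
                    f"{interval.chrom!r} (length {len(chrom_seq)})"
                )
            left_pad = max(0, -lo)
            right_pad = max(0, hi - len(chrom_seq))
            core = chrom_seq[max(0, lo) : min(hi, len(chrom_seq))]
            return "N" * left_pad + core + "N" * right_pad
        return chrom_seq[lo:hi]

    start_win = window(interval.start)
    end_win = window(interval.end)
    if interval.strand == "+":
        seq = start_win + end_win  # acceptor (start) first, donor (end) second
    else:
        # On the minus strand the acceptor sits at the genomic end, so the
        # reverse complement of the plus-strand product already reads
        # acceptor window first in transcript orientation.
        seq = reverse_complement(start_win + end_win)
    return FeatureSequence(sequence=seq, source=interval, flank_len=flank_len)


def build_dataset(
    pos: Sequence[GenomicInterval],
    neg: Sequence[GenomicInterval],
    genome: Genome,
    flank_len: int = 50,
    *,
    pad: bool = False,
) -> LabeledDataset:
    """Extract features for positives (label 1) and negatives (label 0).

    Out-of-bounds extraction failures are dropped with a logged count, and
    duplicate feature sequences are removed (first occurrence kept).
    """
    examples: list[FeatureSequence] = []
    labels: list[int] = []
    n_skipped = 0
    seen: set[str] = set()
    n_dup = 0
    for intervals, y in ((pos, 1), (neg, 0)):
        for iv in intervals:
            try:
                feat = extract_junction_flanks(iv, genome, flank_len, pad=pad)
            except ExtractionError as exc:
                logger.warning("skipping %s: %s", iv.name or iv.chrom, exc)
                n_skipped += 1
                continue
            if feat.sequence in seen:
                n_dup += 1
                continue
            seen.add(feat.sequence)
            examples.append(feat)
            labels.append(y)
    y_arr = np.asarray(labels, dtype=int)
    if not (y_arr == 1).any() or not (y_arr == 0).any():
        raise ValueError(
            "no surviving examples in one class after extraction "
            f"(skipped {n_skipped}, deduplicated {n_dup})"
        )
    if n_skipped:
        logger.info("dropped %d intervals with out-of-bounds windows", n_skipped)
    if n_dup:
        logger.info("removed %d duplicate feature sequences", n_dup)
    return LabeledDataset(examples, y_arr, n_skipped=n_skipped, n_deduplicated=n_dup)


def split_dataset(
    ds: LabeledDataset,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> LabeledDataset:
    """Assign each example to train/validation/test, stratified by label.

    Validation and test sizes are floored per class; the remainder goes to
    train.  Deterministic given the seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    n = len(ds)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    split = np.empty(n, dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(ds.labels == cls)
        if len(idx) < sum(r > 0 for r in ratios):
            raise ValueError(f"class {cls} has fewer examples than requested partitions")
        perm = rng.permutation(idx)
        n_val = int(np.floor(ratios[1] * len(idx)))
        n_test = int(np.floor(ratios[2] * len(idx)))
        split[perm[:n_val]] = "validation"
        split[perm[n_val : n_val + n_test]] = "test"
        split[perm[n_val + n_test :]] = "train"
    ds.split = split
    return ds


def write_features_tsv(path, ds: LabeledDataset) -> None:
    """Two-column TSV (id, sequence) plus the label, for downstream reuse."""
    with open(path, "w") as fh:
        fh.write("id\tsequence\tlabel\n")
        for feat, y in zip(ds.examples, ds.labels):
            fh.write(f"{feat.source.name}\t{feat.sequence}\t{int(y)}\n")
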