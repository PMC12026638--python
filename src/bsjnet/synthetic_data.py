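"""Synthetic genomes and planted-motif interval sets for end-to-end testing.

Real circRNA training data couple a genome FASTA with BED files of
back-splice spans; the discriminative signal concentrates near the two
splice sites.  The generator emulates exactly that handle and nothing more:
an i.i.d. random genome, and labeled intervals where the positive class
carries short splice-site-like motifs written into the genome inside the
two junction flank windows (a donor-site motif starting at the span end and
an acceptor-site motif ending at the span start).  Motif content echoes the
canonical GT/AG splice dinucleotides but is otherwise an arbitrary fixture.

``motif_rate`` scales the fraction of positives carrying the signal (0
yields a null dataset where the classes are statistically identical) and
``label_noise`` flips emitted labels, so learnability can be probed as a
function of signal strength.  Negatives are placement-matched to positives
— same span and slot geometry — so length or composition confounds cannot
leak label information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    Genome,
    GenomicInterval,
    write_bed,
)

BASES = "ACGT"


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset (fully deterministic per seed)."""

    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_pos: int = 100
    n_neg: int = 100
    donor_motif: str = "AGGTAAGT"
    acceptor_motif: str = "TTTAG"
    motif_rate: float = 1.0
    label_noise: float = 0.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    flank_len: int = 50
    span_range: tuple[int, int] = (150, 400)
    record_gap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_rate <= 1.0 and 0.0 <= self.label_noise <= 1.0):
            raise ValueError("motif_rate and label_noise must lie in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if max(len(self.donor_motif), len(self.acceptor_motif)) >= self.flank_len:
            raise ValueError("motifs must be shorter than the flank width")
        if self.span_range[0] < 2 * self.flank_len:
            raise ValueError("minimum span must be at least twice the flank width")

    @property
    def slot_width(self) -> int:
        return self.span_range[1] + 2 * self.flank_len + self.record_gap


def generate_toy_genome(spec: SyntheticSpec) -> Genome:
    """I.i.d. random genome per ``base_composition``, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    records = {
        f"chr{i + 1}": "".join(
            rng.choice(list(BASES), size=spec.chrom_length, p=spec.base_composition)
        )
        for i in range(spec.n_chromosomes)
    }
    return Genome(records)


def plant_records(
    genome: Genome, spec: SyntheticSpec
) -> tuple[Genome, list[GenomicInterval], list[GenomicInterval], pd.DataFrame]:
    """Place labeled intervals and write motifs into positive junctions.

    Records are laid out in non-overlapping slots (shuffled class order) so
    one record's planted motif can never bleed into another's windows.
    Returns the mutated genome, the positive and negative BED record lists
    (post label-noise), and a ground-truth manifest.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_total = spec.n_pos + spec.n_neg
    slots_per_chrom = (spec.chrom_length - 2 * spec.flank_len) // spec.slot_width
    if slots_per_chrom * spec.n_chromosomes < n_total:
        raise ValueError(
            f"too many records for available space: need {n_total} slots, "
            f"have {slots_per_chrom * spec.n_chromosomes}"
        )
    true_labels = np.array([1] * spec.n_pos + [0] * spec.n_neg)
    rng.shuffle(true_labels)
    chrom_seqs = {name: list(seq) for name, seq in genome.records.items()}
    chrom_names = sorted(chrom_seqs)

    pos_out: list[GenomicInterval] = []
    neg_out: list[GenomicInterval] = []
    rows = []
    for i, true_y in enumerate(true_labels):
        chrom = chrom_names[i % spec.n_chromosomes]
        slot = i // spec.n_chromosomes
        slot_base = spec.flank_len + slot * spec.slot_width
        span = int(rng.integers(spec.span_range[0], spec.span_range[1] + 1))
        jitter = int(rng.integers(0, spec.slot_width - span - 2 * spec.flank_len + 1))
        start = slot_base + jitter
        end = start + span
        has_motif = bool(true_y == 1 and rng.random() < spec.motif_rate)
        if has_motif:
            seq = chrom_seqs[chrom]
            # acceptor motif ends at the span start; donor motif begins at the end
            seq[start - len(spec.acceptor_motif) : start] = spec.acceptor_motif
            seq[end : end + len(spec.donor_motif)] = spec.donor_motif
        emitted_y = int(true_y ^ (rng.random() < spec.label_noise))
        name = f"rec{i + 1}"
        label = LABEL_POSITIVE if emitted_y else LABEL_NEGATIVE
        iv = GenomicInterval(chrom=chrom, start=start, end=end, strand="+", name=name, label=label)
        (pos_out if emitted_y else neg_out).append(iv)
        rows.append(
            {
                "id": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "true_label": int(true_y),
                "emitted_label": emitted_y,
                "motif_present": has_motif,
                "acceptor_offset": start - len(spec.acceptor_motif),
                "donor_offset": end,
            }
        )
    mutated = Genome({name: "".join(seq) for name, seq in chrom_seqs.items()})
    return mutated, pos_out, neg_out, pd.DataFrame(rows)


def generate_separable_embeddings(
    n_per_class: int,
    dim: int = 16,
    margin: float = 10.0,
    seed: int = 0,
    n_positions: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Two Gaussian clusters wrapped as (L+2) x D embedding tensors.

    Rows are standard normal noise; class 1 examples additionally carry
    ``margin`` on one fixed coordinate (row 1, column 0), so any linear
    classifier separates the classes perfectly once margin >> noise.
    Returns (X of shape (2n, n_positions + 2, dim), y).
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_positions + 2, dim))
    y = np.array([0] * n_per_class + [1] * n_per_class)
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    X[y == 1, 1, 0] += margin
    return X, y


def write_fasta(path, genome: Genome, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.records):
            fh.write(f">{name}\n")
            seq = genome.records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_dataset(spec: SyntheticSpec, outdir: str | Path | None = None):
    """Generate genome + planted records; optionally write the file bundle.

    The bundle is ``genome.fa``, ``positives.bed``, ``negatives.bed`` and a
    ``manifest.tsv`` holding the ground truth (true label, motif presence,
    motif offsets).
    """
    genome = generate_toy_genome(spec)
    genome, pos, neg, manifest = plant_records(genome, spec)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", genome)
        write_bed(outdir / "positives.bed", pos)
        write_bed(outdir / "negatives.bed", neg)
        manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return genome, pos, neg, manifest
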