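"""Allele-diversity analytics.

Three views of how distinguishable HLA alleles are from short reads:

* per-position Shannon variability across an alignment of allele
  sequences (0 bits = one base observed, 2 bits = all four equally likely);
* mean Hamming distances within and between two-digit groups over the
  peptide-binding exons;
* the unique f-mer analysis: the fraction of alleles carrying at least
  one length-f substring that occurs in no other allele within a mismatch
  tolerance v, on either strand — a proxy for whether reads of length f
  can pin down an allele at all.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aligner import _encode_read, revcomp
from .refdb import ReferenceDB

_BASES = "ACGT"


@dataclass
class VariabilityProfile:
    positions: np.ndarray  # per-column variability, bits in [0, 2]


@dataclass
class DistanceSummary:
    intra: dict[str, float | None]            # group -> mean within-group distance
    inter: dict[tuple[str, str], float]       # (group_a, group_b) -> mean distance


def column_variability(aligned_sequences: Sequence[str]) -> VariabilityProfile:
    """Shannon entropy per column over observed A/C/G/T frequencies.

    Gap (``-``) and ``N`` characters are excluded from the frequencies; a
    column with no A/C/G/T at all scores 0.
    """
    seqs = [s.upper() for s in aligned_sequences]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    mat = np.array([list(s) for s in seqs])
    out = np.zeros(L, dtype=float)
    for j in range(L):
        col = mat[:, j]
        freqs = np.array([(col == b).sum() for b in _BASES], dtype=float)
        tot = freqs.sum()
        if tot == 0:
            continue
        p = freqs[freqs > 0] / tot
        out[j] = float(-(p * np.log2(p)).sum())
    return VariabilityProfile(positions=out)


def hamming(seq_a: str, seq_b: str) -> int:
    """Number of differing positions between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"hamming requires equal lengths ({len(seq_a)} vs {len(seq_b)})")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    return int((a != b).sum())


def _region_seqs(db: ReferenceDB, loci: Iterable[str] | None,
                 region: str) -> list[tuple[str, str]]:
    """(group, sequence) per allele; unequal lengths are right-trimmed to
    the common minimum with a warning."""
    chosen = list(loci) if loci is not None else db.loci
    pairs = []
    for locus in chosen:
        for rec in db.locus_records(locus):
            seq = (rec.peptide_binding_region() if region == "exon23"
                   else rec.subtranscript)
            pairs.append((rec.name.group, seq.upper()))
    if not pairs:
        return []
    lengths = {len(s) for _, s in pairs}
    if len(lengths) > 1:
        m = min(lengths)
        warnings.warn(
            f"sequences of unequal length; right-trimming to {m} nt",
            stacklevel=2)
        pairs = [(g, s[:m]) for g, s in pairs]
    return pairs


def group_distance_summary(
    db: ReferenceDB,
    loci: Iterable[str] | None = None,
    region: str = "exon23",
) -> DistanceSummary:
    """Mean Hamming distance over all within-group and cross-group allele
    pairs (unordered).  Single-member groups have no intra-group distance
    and are reported as ``None``."""
    pairs = _region_seqs(db, loci, region)
    groups: dict[str, list[str]] = {}
    for g, s in pairs:
        groups.setdefault(g, []).append(s)
    intra: dict[str, float | None] = {}
    for g, seqs in groups.items():
        if len(seqs) < 2:
            intra[g] = None
        else:
            dists = [hamming(a, b) for a, b in itertools.combinations(seqs, 2)]
            intra[g] = float(np.mean(dists))
    inter: dict[tuple[str, str], float] = {}
    for ga, gb in itertools.combinations(sorted(groups), 2):
        dists = [hamming(a, b) for a in groups[ga] for b in groups[gb]]
        inter[(ga, gb)] = float(np.mean(dists))
    return DistanceSummary(intra=intra, inter=inter)


# ---------------------------------------------------------------------------
# Unique f-mer analysis


@dataclass(frozen=True)
class FmerConfig:
    f: int          # tag length
    v: int = 0      # mismatch tolerance

    def __post_init__(self) -> None:
        if self.f < 1:
            raise ValueError("f must be >= 1")
        if self.v < 0:
            raise ValueError("v must be >= 0")


def _min_mm_matrix(fmers: np.ndarray, other_codes: np.ndarray,
                   f: int) -> np.ndarray:
    """Minimum mismatch count of each f-mer (rows) against every length-f
    window of ``other_codes``."""
    if len(other_codes) < f:
        return np.full(len(fmers), f + 1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(other_codes, f)
    # (n_fmers, n_windows) mismatch counts; chunk rows to bound memory
    mins = np.empty(len(fmers), dtype=np.int64)
    step = max(1, 4_000_000 // max(1, windows.shape[0] * f))
    for lo in range(0, len(fmers), step):
        block = fmers[lo:lo + step]
        mm = (block[:, None, :] != windows[None, :, :]).sum(axis=2)
        mins[lo:lo + step] = mm.min(axis=1)
    return mins


def unique_fmer_fraction(
    db: ReferenceDB,
    cfg: FmerConfig,
    loci: Iterable[str] | None = None,
    region: str = "exon23",
) -> float:
    """Fraction of alleles in scope with >= 1 unique tag f-mer.

    An f-mer of an allele is unique when it occurs, within <= v mismatches
    and on either strand, in no *other* allele's sequence in scope.
    Sequences shorter than f contribute no f-mers (and cannot be unique).
    """
    pairs = _region_seqs(db, loci, region)
    seqs = [s for _, s in pairs]
    if not seqs:
        return 0.0
    f, v = cfg.f, cfg.v
    codes = [_encode_read(s) for s in seqs]
    rc_codes = [_encode_read(revcomp(s)) for s in seqs]
    n_unique = 0
    short = 0
    for i, s in enumerate(seqs):
        if len(s) < f:
            short += 1
            continue
        fmers = np.lib.stride_tricks.sliding_window_view(codes[i], f)
        alive = np.ones(len(fmers), dtype=bool)
        for j in range(len(seqs)):
            if j == i:
                continue
            for other in (codes[j], rc_codes[j]):
                idx = np.flatnonzero(alive)
                if idx.size == 0:
                    break
                mins = _min_mm_matrix(fmers[idx], other, f)
                alive[idx[mins <= v]] = False
            if not alive.any():
                break
        if alive.any():
            n_unique += 1
    if short:
        warnings.warn(f"{short} sequences shorter than f={f} contribute no f-mers",
                      stacklevel=2)
    return n_unique / len(seqs)


def fmer_grid(
    db: ReferenceDB,
    fs: Sequence[int],
    vs: Sequence[int],
    loci: Iterable[str] | None = None,
):
    """Unique-tag fractions on an f x v grid, as a pandas DataFrame
    (rows = f, columns = v)."""
    import pandas as pd

    data = {v: [unique_fmer_fraction(db, FmerConfig(f=f, v=v), loci=loci)
                for f in fs] for v in vs}
    return pd.DataFrame(data, index=list(fs)).rename_axis(index="f", columns="v")


def plot_variability(profile: VariabilityProfile, ax=None):
    """Simple per-position variability profile plot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(np.arange(1, len(profile.positions) + 1), profile.positions,
            lw=0.8, color="firebrick")
    ax.set_xlabel("alignment position")
    ax.set_ylabel("variability (bits)")
    ax.set_ylim(0, 2.05)
    return ax


def write_variability_tsv(profile: VariabilityProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tvariability_bits\n")
        for i, x in enumerate(profile.positions, 1):
            fh.write(f"{i}\t{x:.4f}\n")


def write_distance_tsv(summary: DistanceSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_a\tgroup_b\tkind\tmean_hamming\n")
        for g, d in summary.intra.items():
            fh.write(f"{g}\t{g}\tintra\t{'NA' if d is None else f'{d:.3f}'}\n")
        for (ga, gb), d in summary.inter.items():
            fh.write(f"{ga}\t{gb}\tinter\t{d:.3f}\n")
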