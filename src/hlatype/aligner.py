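"""Ungapped short-read alignment against the HLA sub-transcript reference.

The mapping contract is deliberately simple: a read aligns at a reference
offset iff the full-length, end-to-end (Hamming) comparison has at most
``v`` substitutions; both strands are searched and every qualifying
placement is reported (``report_policy="all"``) or only reads whose
placements all fall on a single allele are kept (``"unique"``, the
behaviour of a ``-m1``-style mapper).  There are no gaps, no quality
weighting and no insert-size constraint for mate pairs — a pair aligns to
an allele whenever both mates align to it in opposite orientation.

Two implementations of the same contract live here:

* :func:`align_read` / :func:`align_pair` — direct per-allele sliding
  comparison; the reference semantics, fine for small inputs.
* :class:`BulkMapper` — pigeonhole seed-and-extend over many reads at
  once, vectorised with numpy.  It reproduces the brute-force hit set
  exactly (the seed stage can only add candidates, never lose a valid
  placement, because a placement with <= v mismatches must contain at
  least one of v+1 exact read pieces).

``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .refdb import ReferenceDB

_VALID = frozenset("ACGTN")

# base codes: reads and references use distinct codes for N so that N-N
# comparisons count as mismatches
_REF_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_READ_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_REF_TRANS = bytes(_REF_CODE.get(chr(c), 255) for c in range(256))
_READ_TRANS = bytes(_READ_CODE.get(chr(c), 255) for c in range(256))


def _encode_ref(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(_REF_TRANS), dtype=np.uint8)


def _encode_read(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(_READ_TRANS), dtype=np.uint8)


class ReadError(ValueError):
    """A read contains characters outside the A/C/G/T/N alphabet."""


def _check_read(seq: str, read_id: str) -> str:
    seq = seq.upper()
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ReadError(f"read {read_id!r} contains non-ACGTN characters: {bad}")
    return seq


@dataclass(frozen=True)
class AlignerConfig:
    """Mapping parameters.

    Defaults follow the settings the typing algorithm was tuned on:
    one allowed mismatch, report all placements, paired-end input.
    """

    v: int = 1
    report_policy: str = "all"  # "all" | "unique"
    paired: bool = True

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("mismatch budget v must be >= 0")
        if self.report_policy not in ("all", "unique"):
            raise ValueError(f"unknown report_policy {self.report_policy!r}")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    allele_index: int
    offset: int  # 0-based start on the sub-transcript
    strand: str  # "+" | "-"
    mismatches: int


@dataclass(frozen=True)
class PairHit:
    pair_id: str
    allele_index: int
    hit1: AlignmentHit
    hit2: AlignmentHit


def _db_ref_codes(db: ReferenceDB) -> list[np.ndarray]:
    codes = getattr(db, "_ref_codes", None)
    if codes is None or len(codes) != len(db.records):
        codes = [_encode_ref(rec.subtranscript.upper()) for rec in db.records]
        db._ref_codes = codes  # cached; records are not mutated after build
    return codes


def _window_mismatches(read_codes: np.ndarray, ref_codes: np.ndarray) -> np.ndarray:
    """Mismatch count of the read against every offset of one reference."""
    n, L = len(read_codes), len(ref_codes)
    if n > L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(ref_codes, n)
    return (windows != read_codes).sum(axis=1)


def align_read(
    read_sequence: str,
    db: ReferenceDB,
    cfg: AlignerConfig,
    read_id: str = "read",
) -> list[AlignmentHit]:
    """All ungapped placements of one read with <= cfg.v mismatches.

    The reverse strand compares the reverse complement of the read.  With
    ``report_policy="unique"`` the hit list is returned only when all hits
    share one allele; otherwise the empty list.
    """
    seq = _check_read(read_sequence, read_id)
    fwd = _encode_read(seq)
    rev = _encode_read(revcomp(seq))
    hits: list[AlignmentHit] = []
    for ai, ref in enumerate(_db_ref_codes(db)):
        for strand, codes in (("+", fwd), ("-", rev)):
            mm = _window_mismatches(codes, ref)
            for off in np.flatnonzero(mm <= cfg.v):
                hits.append(AlignmentHit(read_id, ai, int(off), strand, int(mm[off])))
    if cfg.report_policy == "unique" and len({h.allele_index for h in hits}) > 1:
        return []
    return hits


def align_pair(
    seq1: str,
    seq2: str,
    db: ReferenceDB,
    cfg: AlignerConfig,
    pair_id: str = "pair",
) -> list[PairHit]:
    """Pair placements: both mates on the same allele, opposite strands.

    No insert-size constraint.  ``report_policy="unique"`` applies at the
    pair level: the list is returned only if every PairHit falls on one
    allele.
    """
    sub = AlignerConfig(v=cfg.v, report_policy="all", paired=True)
    h1 = align_read(seq1, db, sub, read_id=f"{pair_id}/1")
    h2 = align_read(seq2, db, sub, read_id=f"{pair_id}/2")
    by_allele: dict[int, list[AlignmentHit]] = {}
    for h in h2:
        by_allele.setdefault(h.allele_index, []).append(h)
    pairs: list[PairHit] = []
    for a in h1:
        for b in by_allele.get(a.allele_index, []):
            if a.strand != b.strand:
                pairs.append(PairHit(pair_id, a.allele_index, a, b))
    if cfg.report_policy == "unique" and len({p.allele_index for p in pairs}) > 1:
        return []
    return pairs


# ---------------------------------------------------------------------------
# Read-count distributions


@dataclass
class ReadCountDistribution:
    """Per-locus map group -> allele -> fragment count for one iteration.

    Every allele of the locus appears (zero counts included); the median
    across these counts is the zygosity decision threshold.
    """

    locus: str
    iteration: int
    counts: dict[str, dict[str, int]]

    def allele_counts(self) -> list[tuple[str, str, int]]:
        """Flat ``(group, allele, count)`` rows in insertion order."""
        return [(g, a, c) for g, inner in self.counts.items()
                for a, c in inner.items()]

    def values(self) -> np.ndarray:
        return np.array([c for _, _, c in self.allele_counts()], dtype=float)

    def group_values(self) -> dict[str, int]:
        """Per-group read count: the count of the group's best-supported
        allele (the value the calling formulas operate on)."""
        return {g: (max(inner.values()) if inner else 0)
                for g, inner in self.counts.items()}

    def total(self) -> int:
        return int(self.values().sum())


def _empty_counts(db: ReferenceDB, locus: str) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {}
    for rec in db.locus_records(locus):
        counts.setdefault(rec.name.group, {})[rec.name.raw_name] = 0
    return counts


def count_reads(
    read_hits: Mapping[str, Sequence[AlignmentHit | PairHit]],
    db: ReferenceDB,
    locus: str,
    iteration: int = 1,
) -> ReadCountDistribution:
    """Tally fragments per allele: a fragment increments every allele it
    hits at least once (a mate pair counts as one unit)."""
    counts = _empty_counts(db, locus)
    for _, hits in read_hits.items():
        alleles = {h.allele_index for h in hits}
        for ai in alleles:
            name = db.records[ai].name
            if name.locus == locus:
                counts[name.group][name.raw_name] += 1
    return ReadCountDistribution(locus=locus, iteration=iteration, counts=counts)


# ---------------------------------------------------------------------------
# Bulk seed-and-extend mapper

_NO_HIT = np.uint8(255)


@dataclass
class MappingResult:
    """Sparse per-(fragment, allele) best-mismatch table for one sample.

    ``pm`` is the paired mismatch level: the smallest m such that both
    mates place on the allele in opposite orientation with <= m mismatches
    each.  ``m1`` is the best single-end mismatch count of mate 1 alone
    (used to emulate single-end sequencing from the same fragments).  255
    means "no placement within the mapper's budget".
    """

    db: ReferenceDB
    n_fragments: int
    vmax: int
    frag: np.ndarray   # int32
    allele: np.ndarray  # int32
    pm: np.ndarray     # uint8
    m1: np.ndarray     # uint8
    paired_input: bool = True

    def _valid_rows(self, v: int, paired: bool) -> np.ndarray:
        if v > self.vmax:
            raise ValueError(f"v={v} exceeds the mapper budget vmax={self.vmax}")
        mm = self.pm if paired else self.m1
        return mm <= v

    def _policy_rows(self, cfg: AlignerConfig) -> np.ndarray:
        sel = self._valid_rows(cfg.v, cfg.paired)
        if cfg.report_policy == "unique":
            per_frag = np.bincount(self.frag[sel], minlength=self.n_fragments)
            sel = sel & (per_frag[self.frag] == 1)
        return sel

    def counts(
        self,
        locus: str,
        cfg: AlignerConfig,
        iteration: int = 1,
        exclude_fragments: np.ndarray | None = None,
    ) -> ReadCountDistribution:
        """Fragment counts per allele of ``locus`` under ``cfg``;
        ``exclude_fragments`` is a boolean mask of fragments to drop
        (iteration-2 removal)."""
        sel = self._policy_rows(cfg)
        if exclude_fragments is not None:
            sel = sel & ~exclude_fragments[self.frag]
        per_allele = np.bincount(self.allele[sel], minlength=len(self.db.records))
        counts = _empty_counts(self.db, locus)
        for i in self.db.by_locus.get(locus, []):
            name = self.db.records[i].name
            counts[name.group][name.raw_name] = int(per_allele[i])
        return ReadCountDistribution(locus=locus, iteration=iteration, counts=counts)

    def fragments_hitting_group(self, locus: str, group: str,
                                cfg: AlignerConfig) -> np.ndarray:
        """Boolean mask over fragments with >= 1 valid hit on any allele of
        ``group`` at ``locus``."""
        sel = self._policy_rows(cfg)
        in_group = np.zeros(len(self.db.records), dtype=bool)
        for i in self.db.by_locus.get(locus, []):
            if self.db.records[i].name.group == group:
                in_group[i] = True
        sel = sel & in_group[self.allele]
        mask = np.zeros(self.n_fragments, dtype=bool)
        mask[self.frag[sel]] = True
        return mask

    def allele_sets(self, cfg: AlignerConfig) -> list[set[int]]:
        """Per-fragment set of allele indices hit under ``cfg`` (testing aid)."""
        sel = self._policy_rows(cfg)
        out: list[set[int]] = [set() for _ in range(self.n_fragments)]
        for f, a in zip(self.frag[sel], self.allele[sel]):
            out[f].add(int(a))
        return out


def _min_by_key(keys: np.ndarray, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group int64 keys and take the minimum value per key."""
    if keys.size == 0:
        return keys, vals
    order = np.argsort(keys, kind="stable")
    k, v = keys[order], vals[order]
    starts = np.flatnonzero(np.r_[True, k[1:] != k[:-1]])
    return k[starts], np.minimum.reduceat(v, starts)


def _max_on_common(k1, v1, k2, v2) -> tuple[np.ndarray, np.ndarray]:
    """max(v1, v2) on the intersection of two unique-key tables."""
    common, i1, i2 = np.intersect1d(k1, k2, assume_unique=True,
                                    return_indices=True)
    return common, np.maximum(v1[i1], v2[i2])


def _min_union(k1, v1, k2, v2) -> tuple[np.ndarray, np.ndarray]:
    return _min_by_key(np.concatenate([k1, k2]), np.concatenate([v1, v2]))


class BulkMapper:
    """Seed-and-extend mapper over a fixed reference database.

    For a mismatch budget ``vmax`` every read is split into ``vmax + 1``
    contiguous pieces; a valid placement must match at least one piece
    exactly, so exact-match lookups of the pieces in a reference substring
    index enumerate a candidate superset, which is then verified by direct
    Hamming counting.  Equivalent to the brute-force scan, but vectorised.
    """

    def __init__(self, db: ReferenceDB, vmax: int = 2):
        self.db = db
        self.vmax = int(vmax)
        self.seqs = [rec.subtranscript.upper() for rec in db.records]
        self.lengths = np.array([len(s) for s in self.seqs], dtype=np.int64)
        self.stride = int(self.lengths.max()) + 1 if len(self.seqs) else 1
        self.starts = np.zeros(len(self.seqs) + 1, dtype=np.int64)
        np.cumsum(self.lengths, out=self.starts[1:])
        self.refcat = (np.concatenate([_encode_ref(s) for s in self.seqs])
                       if self.seqs else np.empty(0, dtype=np.uint8))
        self._piece_cache: dict[int, list[tuple[int, int]]] = {}
        self._seed_cache: dict[int, dict[bytes, np.ndarray]] = {}

    # -- seed index -------------------------------------------------------

    def _pieces(self, read_length: int) -> list[tuple[int, int]]:
        pieces = self._piece_cache.get(read_length)
        if pieces is None:
            k = self.vmax + 1
            bounds = np.linspace(0, read_length, k + 1).astype(int)
            pieces = [(int(bounds[j]), int(bounds[j + 1] - bounds[j]))
                      for j in range(k) if bounds[j + 1] > bounds[j]]
            self._piece_cache[read_length] = pieces
        return pieces

    def _seed_index(self, plen: int) -> dict[bytes, np.ndarray]:
        """All reference substrings of length ``plen`` -> packed
        (allele * stride + position) arrays."""
        index = self._seed_cache.get(plen)
        if index is not None:
            return index
        tmp: dict[bytes, list[int]] = {}
        for ai, seq in enumerate(self.seqs):
            b = seq.encode()
            base = ai * self.stride
            for pos in range(len(b) - plen + 1):
                tmp.setdefault(b[pos:pos + plen], []).append(base + pos)
        index = {k: np.array(v, dtype=np.int64) for k, v in tmp.items()}
        self._seed_cache[plen] = index
        return index

    # -- candidate generation + verification ------------------------------

    def _strand_min_mm(self, seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Best mismatch count per (read, allele) for the given oriented
        sequences, as a (unique int64 key = read * n_alleles + allele,
        uint8 min-mm) table.  Only placements with <= vmax mismatches
        appear."""
        n_alleles = len(self.seqs)
        cand_packed: list[np.ndarray] = []
        cand_read: list[int] = []
        cand_sizes: list[int] = []
        by_len: dict[int, list[tuple[int, int, dict]]] = {}
        for i, s in enumerate(seqs):
            n = len(s)
            specs = by_len.get(n)
            if specs is None:
                specs = [(sj, lj, self._seed_index(lj)) for sj, lj in self._pieces(n)]
                by_len[n] = specs
            for sj, lj, index in specs:
                arr = index.get(s[sj:sj + lj].encode())
                if arr is not None:
                    cand_packed.append(arr - sj)  # packed candidate offset
                    cand_read.append(i)
                    cand_sizes.append(arr.size)
        if not cand_packed:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
        packed = np.concatenate(cand_packed)
        read_idx = np.repeat(np.array(cand_read, dtype=np.int64),
                             np.array(cand_sizes, dtype=np.int64))
        # drop negative offsets (piece started before the reference) and
        # deduplicate (read, allele, offset)
        keep = packed >= 0
        packed, read_idx = packed[keep], read_idx[keep]
        key = np.unique(read_idx * (n_alleles * self.stride) + packed)
        read_idx = key // (n_alleles * self.stride)
        packed = key % (n_alleles * self.stride)
        allele = packed // self.stride
        offset = packed % self.stride

        read_lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        n_of = read_lengths[read_idx]
        keep = offset + n_of <= self.lengths[allele]
        read_idx, allele, offset, n_of = (read_idx[keep], allele[keep],
                                          offset[keep], n_of[keep])

        # verify candidates in batches, grouped by read length
        mm = np.empty(read_idx.size, dtype=np.int32)
        for n in np.unique(n_of):
            rows = np.flatnonzero(n_of == n)
            codes = np.zeros((len(seqs), int(n)), dtype=np.uint8)
            for i in np.unique(read_idx[rows]):
                codes[i] = _encode_read(seqs[i])
            for lo in range(0, rows.size, 1_000_000):
                chunk = rows[lo:lo + 1_000_000]
                pos = (self.starts[allele[chunk]] + offset[chunk])[:, None] \
                    + np.arange(int(n), dtype=np.int64)[None, :]
                ref_win = self.refcat[pos]
                rd = codes[read_idx[chunk]]
                mm[chunk] = (ref_win != rd).sum(axis=1, dtype=np.int32)
        keep = mm <= self.vmax
        key2 = read_idx[keep] * n_alleles + allele[keep]
        return _min_by_key(key2, mm[keep].astype(np.uint8))

    def map_fragments(
        self,
        seqs1: Sequence[str],
        seqs2: Sequence[str] | None = None,
        read_ids: Sequence[str] | None = None,
    ) -> MappingResult:
        """Map a batch of fragments (mate 1 sequences, optional mate 2).

        Reads are validated against the A/C/G/T/N alphabet.  Returns the
        sparse best-mismatch table from which counts at any ``v <= vmax``
        and either report policy can be derived.
        """
        ids = read_ids or [f"frag{i}" for i in range(len(seqs1))]
        seqs1 = [_check_read(s, f"{rid}/1") for s, rid in zip(seqs1, ids)]
        paired = seqs2 is not None
        if paired:
            if len(seqs2) != len(seqs1):
                raise ValueError("mate files have unequal read counts")
            seqs2 = [_check_read(s, f"{rid}/2") for s, rid in zip(seqs2, ids)]
        n_alleles = len(self.seqs)
        n_frag = len(seqs1)

        k1p, v1p = self._strand_min_mm(seqs1)
        k1m, v1m = self._strand_min_mm([revcomp(s) for s in seqs1])
        km1, vm1 = _min_union(k1p, v1p, k1m, v1m)  # mate1 single-end table
        if paired:
            k2p, v2p = self._strand_min_mm(seqs2)
            k2m, v2m = self._strand_min_mm([revcomp(s) for s in seqs2])
            kfr, vfr = _max_on_common(k1p, v1p, k2m, v2m)  # mate1 fwd / mate2 rev
            krf, vrf = _max_on_common(k1m, v1m, k2p, v2p)
            kpm, vpm = _min_union(kfr, vfr, krf, vrf)
        else:
            kpm = np.empty(0, dtype=np.int64)
            vpm = np.empty(0, dtype=np.uint8)

        all_keys = np.union1d(km1, kpm)
        pm = np.full(all_keys.size, _NO_HIT, dtype=np.uint8)
        m1 = np.full(all_keys.size, _NO_HIT, dtype=np.uint8)
        pm[np.searchsorted(all_keys, kpm)] = vpm
        m1[np.searchsorted(all_keys, km1)] = vm1
        return MappingResult(
            db=self.db, n_fragments=n_frag, vmax=self.vmax,
            frag=(all_keys // n_alleles).astype(np.int32),
            allele=(all_keys % n_alleles).astype(np.int32),
            pm=pm, m1=m1, paired_input=paired,
        )


def mapping_from_hits(
    read_hits: Mapping[str, Sequence[AlignmentHit | PairHit]],
    db: ReferenceDB,
    vmax: int = 2,
) -> tuple[MappingResult, list[str]]:
    """Build a :class:`MappingResult` from explicit per-read hit lists
    (spec-style plumbing for small inputs and tests).  Returns the result
    and the fragment-index -> read-id order used."""
    order = list(read_hits)
    rows: dict[tuple[int, int], int] = {}
    for f, rid in enumerate(order):
        for h in read_hits[rid]:
            if isinstance(h, PairHit):
                mm = max(h.hit1.mismatches, h.hit2.mismatches)
            else:
                mm = h.mismatches
            key = (f, h.allele_index)
            rows[key] = min(rows.get(key, 255), mm)
    frag = np.array([k[0] for k in rows], dtype=np.int32)
    allele = np.array([k[1] for k in rows], dtype=np.int32)
    mm = np.array(list(rows.values()), dtype=np.uint8)
    return MappingResult(db=db, n_fragments=len(order), vmax=vmax,
                         frag=frag, allele=allele, pm=mm.copy(), m1=mm.copy()), order
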