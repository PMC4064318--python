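"""Seeded generator of HLA-like allele databases and diploid RNA-Seq reads.

The generator emulates the structure that makes HLA typing from short
reads hard: a multi-locus gene family with strong cross-locus
conservation, moderate divergence between two-digit groups and very high
similarity within a group.  Sequences are produced hierarchically — a
single ancestral sequence, per-locus ancestors, per-group founders,
per-allele leaves — with an independent substitution rate at each level,
so two siblings at rate ``r`` differ at ``~2r - (4/3)r^2`` of their
positions in expectation.

Reads are drawn uniformly along the sub-transcripts of a diploid genotype
(two allele picks per locus, possibly identical), as fixed-length mate
pairs from the two fragment ends in opposite orientation, with i.i.d.
per-base substitution errors.  Every fragment's source allele is recorded
in its read id and in the truth table, so recovery can be scored exactly.

Default parameters are the study conditions used throughout the test
suite: 6 loci (A, B, C, DQA1, DQB1, DRB1), 8 groups x 5 alleles per
locus, class I exon lengths giving 694-nt sub-transcripts, 0.5 % / 3 % /
8 % intra-group / inter-group / cross-locus substitution rates, 37-nt
paired-end reads at 1 % sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .refdb import (AlleleRecord, ReferenceDB, build_subtranscript,
                    parse_allele_name)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LocusSpec:
    name: str
    hla_class: str
    exon_lengths: tuple[int, ...]  # full exon lengths before flank trimming


#: exon lengths chosen so the assembled sub-transcripts have the canonical
#: lengths: class I 73+270+276+75 = 694 nt; DQA1 75+250+75 = 400 nt;
#: DQB1/DRB1 75+271+75 = 421 nt (flanking exons are generated longer than
#: the retained 75 nt, as in real annotations)
DEFAULT_LOCI = (
    LocusSpec("A", "I", (73, 270, 276, 90)),
    LocusSpec("B", "I", (73, 270, 276, 90)),
    LocusSpec("C", "I", (73, 270, 276, 90)),
    LocusSpec("DQA1", "II", (90, 250, 90)),
    LocusSpec("DQB1", "II", (90, 271, 90)),
    LocusSpec("DRB1", "II", (90, 271, 90)),
)


@dataclass(frozen=True)
class DbSimConfig:
    """Parameters of the synthetic allele database."""

    seed: int
    loci: tuple[LocusSpec, ...] = DEFAULT_LOCI
    groups_per_locus: int = 8
    alleles_per_group: int = 5
    inter_group_divergence: float = 0.03
    intra_group_divergence: float = 0.005
    cross_locus_divergence: float = 0.08

    def __post_init__(self) -> None:
        if not (0 <= self.intra_group_divergence < self.inter_group_divergence
                <= self.cross_locus_divergence <= 1):
            raise ValueError(
                "divergence ordering violated: need 0 <= intra < inter <= cross <= 1")
        if self.groups_per_locus < 1 or self.alleles_per_group < 1:
            raise ValueError("group/allele counts must be >= 1")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a
    different base)."""
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def make_allele_db(cfg: DbSimConfig) -> tuple[ReferenceDB, dict]:
    """Generate the allele database.

    Returns the :class:`ReferenceDB` (records carry exon annotations and
    assembled sub-transcripts) plus an ancestry dict with the master,
    per-locus ancestor and per-group founder sequences.  Deterministic
    under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    max_len = max(sum(sp.exon_lengths) for sp in cfg.loci)
    master = rng.integers(0, 4, size=max_len).astype(np.uint8)
    ancestry: dict = {"master": _decode(master), "locus_ancestors": {},
                      "group_founders": {}}
    records: list[AlleleRecord] = []
    for sp in cfg.loci:
        total = sum(sp.exon_lengths)
        ancestor = _mutate(master[:total], cfg.cross_locus_divergence, rng)
        ancestry["locus_ancestors"][sp.name] = _decode(ancestor)
        ancestry["group_founders"][sp.name] = {}
        for g in range(1, cfg.groups_per_locus + 1):
            founder = _mutate(ancestor, cfg.inter_group_divergence, rng)
            group = f"{sp.name}*{g:02d}"
            ancestry["group_founders"][sp.name][group] = _decode(founder)
            for a in range(1, cfg.alleles_per_group + 1):
                allele = _mutate(founder, cfg.intra_group_divergence, rng)
                seq = _decode(allele)
                exons: list[tuple[int, str]] = []
                pos = 0
                for idx, ln in enumerate(sp.exon_lengths, 1):
                    exons.append((idx, seq[pos:pos + ln]))
                    pos += ln
                rec = AlleleRecord(
                    name=parse_allele_name(f"{sp.name}*{g:02d}:{a:02d}"),
                    exons=exons)
                build_subtranscript(rec, sp.hla_class)
                records.append(rec)
    return ReferenceDB.from_records(records), ancestry


def write_db_inputs(db: ReferenceDB, fasta_path: str | Path,
                    exon_table_path: str | Path) -> None:
    """Emit the raw allele FASTA (concatenated exons) and the exon TSV in
    the dialect the reference parser reads, so the database round-trips
    through the normal build path."""
    with open(fasta_path, "w") as fa, open(exon_table_path, "w") as tsv:
        tsv.write("name\texon_index\tstart\tend\n")
        for rec in db.records:
            full = "".join(seq for _, seq in rec.exons)
            fa.write(f">{rec.name.raw_name}\n")
            for lo in range(0, len(full), 70):
                fa.write(full[lo:lo + 70] + "\n")
            pos = 1
            for idx, seq in rec.exons:
                tsv.write(f"{rec.name.raw_name}\t{idx}\t{pos}\t{pos + len(seq) - 1}\n")
                pos += len(seq)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of one simulated sample's read set."""

    seed: int
    genotype: dict  # locus -> (allele_name, allele_name); equal names = homozygous
    fragments_per_locus: int | dict = 2000
    read_length: int = 37
    paired: bool = True
    fragment_mean: float = 150.0
    fragment_sd: float = 30.0
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class TruthTable:
    """Ground truth for one simulated sample."""

    sample_id: str
    groups: dict[str, tuple[str, str]]       # locus -> sorted group pair
    alleles: dict[str, tuple[str, str]]      # locus -> allele name pair
    zygosity: dict[str, str]                 # locus -> heterozygous|homozygous
    fragments: dict[str, int]                # locus -> fragment count
    sources: list[tuple[str, str]]           # per fragment (locus, allele)


@dataclass
class SimReads:
    """In-memory simulated read set (mate2 is ``None`` for single-end)."""

    ids: list[str]
    reads1: list[str]
    reads2: list[str] | None
    truth: TruthTable

    def single_end(self) -> "SimReads":
        """The same fragments sequenced single-end (mate 1 only)."""
        return SimReads(ids=self.ids, reads1=self.reads1, reads2=None,
                        truth=self.truth)


def simulate_fragments(db: ReferenceDB, cfg: ReadSimConfig,
                       sample_id: str = "sample") -> SimReads:
    """Draw reads for one sample; deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    by_name = {rec.name.raw_name: rec for rec in db.records}
    codes: dict[str, np.ndarray] = {}
    for locus, picks in cfg.genotype.items():
        for name in picks:
            if name not in by_name:
                raise ValueError(f"genotype allele {name!r} not in the reference")
            rec = by_name[name]
            if cfg.read_length > rec.length_nt:
                raise ValueError(
                    f"read_length {cfg.read_length} exceeds sub-transcript of {name}")
            codes[name] = np.frombuffer(
                rec.subtranscript.encode().translate(
                    bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))),
                dtype=np.uint8).copy()

    ids: list[str] = []
    reads1: list[str] = []
    reads2: list[str] = []
    sources: list[tuple[str, str]] = []
    fragments: dict[str, int] = {}
    groups: dict[str, tuple[str, str]] = {}
    alleles: dict[str, tuple[str, str]] = {}
    zygo: dict[str, str] = {}
    rl = cfg.read_length
    for locus in sorted(cfg.genotype):
        a1, a2 = cfg.genotype[locus]
        g1 = by_name[a1].name.group
        g2 = by_name[a2].name.group
        groups[locus] = tuple(sorted((g1, g2)))
        alleles[locus] = (a1, a2)
        zygo[locus] = "homozygous" if g1 == g2 else "heterozygous"
        n = (cfg.fragments_per_locus[locus]
             if isinstance(cfg.fragments_per_locus, dict)
             else cfg.fragments_per_locus)
        fragments[locus] = n
        which = rng.integers(0, 2, size=n)
        for k in range(n):
            name = (a1, a2)[which[k]]
            sub = codes[name]
            L = sub.size
            flen = int(np.clip(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)),
                               rl, L))
            start = int(rng.integers(0, L - flen + 1))
            frag = sub[start:start + flen]
            if cfg.error_rate > 0:
                frag = _mutate(frag, cfg.error_rate, rng)
            m_a = frag[:rl]
            m_b = (3 - frag[-rl:])[::-1]  # reverse complement of the far end
            flip = rng.random() < 0.5  # fragment sequenced from the minus strand
            if flip:
                m_a, m_b = m_b, m_a
            # id encodes the source coordinates ('|'-separated; allele names
            # contain ':') so recovery and error rates can be recounted
            fid = (f"{sample_id}|{locus}|{name}|{k}|{start}|{flen}|"
                   f"{'-' if flip else '+'}")
            ids.append(fid)
            reads1.append(_decode(m_a))
            reads2.append(_decode(m_b))
            sources.append((locus, name))
    truth = TruthTable(sample_id=sample_id, groups=groups, alleles=alleles,
                       zygosity=zygo, fragments=fragments, sources=sources)
    return SimReads(ids=ids, reads1=reads1,
                    reads2=reads2 if cfg.paired else None, truth=truth)


def write_fastq(path: str | Path, ids: Sequence[str],
                seqs: Sequence[str], mate: int | None = None) -> None:
    suffix = f"/{mate}" if mate else ""
    with open(path, "w") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}{suffix}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlocus\tgroup1\tgroup2\tallele1\tallele2\t"
                 "zygosity\tfragments\n")
        for locus in truth.groups:
            g1, g2 = truth.groups[locus]
            a1, a2 = truth.alleles[locus]
            fh.write(f"{truth.sample_id}\t{locus}\t{g1}\t{g2}\t{a1}\t{a2}\t"
                     f"{truth.zygosity[locus]}\t{truth.fragments[locus]}\n")


def simulate_reads(
    db: ReferenceDB,
    cfg: ReadSimConfig,
    out_dir: str | Path,
    sample_id: str = "sample",
) -> tuple[tuple[Path, ...], TruthTable]:
    """File-based variant of :func:`simulate_fragments`: writes FASTQ
    file(s) and a truth TSV into ``out_dir`` and returns their paths with
    the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_fragments(db, cfg, sample_id=sample_id)
    write_truth_tsv(sim.truth, out / f"{sample_id}.truth.tsv")
    if sim.reads2 is not None:
        p1 = out / f"{sample_id}_1.fastq"
        p2 = out / f"{sample_id}_2.fastq"
        write_fastq(p1, sim.ids, sim.reads1, mate=1)
        write_fastq(p2, sim.ids, sim.reads2, mate=2)
        return (p1, p2), sim.truth
    p1 = out / f"{sample_id}.fastq"
    write_fastq(p1, sim.ids, sim.reads1)
    return (p1,), sim.truth


# ---------------------------------------------------------------------------
# Genotype and cohort helpers


def random_genotype(db: ReferenceDB, rng: np.random.Generator,
                    hom_prob: float = 0.25) -> dict[str, tuple[str, str]]:
    """Random diploid genotype: per locus one allele, then with probability
    ``hom_prob`` the same allele again (group-level homozygous), otherwise
    an allele from a different group."""
    genotype: dict[str, tuple[str, str]] = {}
    for locus in db.loci:
        recs = db.locus_records(locus)
        first = recs[int(rng.integers(0, len(recs)))]
        if rng.random() < hom_prob:
            genotype[locus] = (first.name.raw_name, first.name.raw_name)
        else:
            others = [r for r in recs if r.name.group != first.name.group]
            second = others[int(rng.integers(0, len(others)))]
            genotype[locus] = (first.name.raw_name, second.name.raw_name)
    return genotype


def simulate_cohort(
    db: ReferenceDB,
    n_individuals: int,
    seed: int,
    fragments_per_locus: int | dict = 2000,
    hom_prob: float = 0.25,
    **read_cfg_kwargs,
) -> list[SimReads]:
    """Simulate a cohort of diploid individuals with random genotypes.

    Per-individual seeds are derived deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_individuals):
        genotype = random_genotype(db, rng, hom_prob=hom_prob)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = ReadSimConfig(seed=sub_seed, genotype=genotype,
                            fragments_per_locus=fragments_per_locus,
                            **read_cfg_kwargs)
        cohort.append(simulate_fragments(db, cfg, sample_id=f"ind{i:02d}"))
    return cohort
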