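"""Locus-level HLA expression from the genotyped groups.

Cross-reactive reads are unavoidable: the loci are paralogous and the
alleles within a locus nearly identical, so a fragment frequently maps to
several of the *determined* groups (the genotype called for the sample).
Each fragment is therefore split proportionally — 1/k of a count to each
of the k determined groups it maps to — and the per-locus totals are
normalized to reads per kilobase of sub-transcript per million fragments
(RPKM).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .aligner import MappingResult
from .refdb import CLASS_I_LOCI, CLASS_II_LOCI
from .typer import HETEROZYGOUS, HlaType


@dataclass
class ExpressionRecord:
    locus: str
    fractional_count: float
    subtranscript_length_nt: float
    total_reads_millions: float
    rpkm: float


@dataclass
class ExpressionProfile:
    sample_id: str
    records: dict[str, ExpressionRecord]

    def class_total(self, hla_class: str) -> float:
        loci = CLASS_I_LOCI if hla_class == "I" else CLASS_II_LOCI
        return sum(r.rpkm for l, r in self.records.items() if l in loci)


def proportional_assignment(
    read_to_groups: Mapping[str, set[str]],
) -> dict[str, float]:
    """Fractional per-locus counts from read -> determined-group sets.

    A read mapping to k determined groups contributes 1/k to each; its
    locus is the gene-name part of the group string (e.g. ``A*01`` -> A).
    Reads mapping to no determined group contribute nothing.
    """
    out: dict[str, float] = {}
    for _, groups in read_to_groups.items():
        k = len(groups)
        if k == 0:
            continue
        w = 1.0 / k
        for g in groups:
            locus = g.split("*", 1)[0]
            out[locus] = out.get(locus, 0.0) + w
    return out


def rpkm(fractional_count: float, length_nt: float, total_reads: float) -> float:
    """Reads per kilobase of (sub-transcript) model per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("length_nt must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return fractional_count / ((length_nt / 1000.0) * (total_reads / 1e6))


def _determined_groups(hla_type: HlaType) -> dict[str, set[str]]:
    """Per-locus groups making up the called genotype: the first call,
    plus the second when the locus is heterozygous.  Ambiguous loci keep
    only the first (conservative)."""
    det: dict[str, set[str]] = {}
    for locus, lc in hla_type.locus_calls.items():
        if lc.is_no_call:
            continue
        groups = {lc.call1.group}
        if lc.zygosity.status == HETEROZYGOUS and lc.call2 is not None:
            groups.add(lc.call2.group)
        det[locus] = groups
    return det


def expression_profile(
    mapping: MappingResult,
    hla_type: HlaType,
    total_reads: int | None = None,
) -> ExpressionProfile:
    """Per-locus fractional counts and RPKM for a typed sample.

    ``total_reads`` defaults to the number of input fragments (the mapper
    only sees HLA reads); pass a library-wide mapped-fragment total to
    normalize against the whole transcriptome instead.  The normalization
    length of a locus is the mean sub-transcript length over the alleles
    of its determined groups.
    """
    db = mapping.db
    cfg = hla_type.config
    determined = _determined_groups(hla_type)
    total = total_reads if total_reads is not None else mapping.n_fragments

    # map allele index -> small integer id of its (locus, group) if determined
    group_ids: dict[tuple[str, str], int] = {}
    allele_gid = np.full(len(db.records), -1, dtype=np.int64)
    for locus, groups in determined.items():
        for g in groups:
            group_ids[(locus, g)] = len(group_ids)
    for i, rec in enumerate(db.records):
        gid = group_ids.get((rec.name.locus, rec.name.group))
        if gid is not None:
            allele_gid[i] = gid

    sel = mapping._policy_rows(cfg)
    sel = sel & (allele_gid[mapping.allele] >= 0)
    n_g = max(len(group_ids), 1)
    pair_keys = np.unique(
        mapping.frag[sel].astype(np.int64) * n_g + allele_gid[mapping.allele[sel]])
    frag_of = pair_keys // n_g
    gid_of = pair_keys % n_g
    per_frag = np.bincount(frag_of, minlength=mapping.n_fragments)
    weights = 1.0 / per_frag[frag_of]

    gid_locus = {gid: locus for (locus, _), gid in group_ids.items()}
    frac: dict[str, float] = {locus: 0.0 for locus in hla_type.locus_calls}
    per_gid = np.bincount(gid_of, weights=weights, minlength=n_g)
    for gid, locus in gid_locus.items():
        frac[locus] = frac.get(locus, 0.0) + float(per_gid[gid])

    records: dict[str, ExpressionRecord] = {}
    for locus in hla_type.locus_calls:
        groups = determined.get(locus, set())
        lengths = [rec.length_nt for rec in db.locus_records(locus)
                   if rec.name.group in groups]
        length = float(np.mean(lengths)) if lengths else float(np.mean(
            [rec.length_nt for rec in db.locus_records(locus)] or [1]))
        count = frac.get(locus, 0.0)
        records[locus] = ExpressionRecord(
            locus=locus,
            fractional_count=count,
            subtranscript_length_nt=length,
            total_reads_millions=total / 1e6,
            rpkm=rpkm(count, length, total),
        )
    return ExpressionProfile(sample_id=hla_type.sample_id, records=records)


def write_expression_report(profile: ExpressionProfile, path: str | Path) -> None:
    """TSV: per-locus fractional count, length, totals and RPKM, plus the
    class I / class II summed-RPKM summary rows."""
    with open(path, "w") as fh:
        fh.write("sample_id\tlocus\tfractional_count\tlength_nt\t"
                 "total_reads\trpkm\n")
        for locus, r in profile.records.items():
            fh.write(f"{profile.sample_id}\t{locus}\t{r.fractional_count:.3f}\t"
                     f"{r.subtranscript_length_nt:.1f}\t"
                     f"{r.total_reads_millions * 1e6:.0f}\t{r.rpkm:.4f}\n")
        fh.write(f"{profile.sample_id}\tclassI_sum\t\t\t\t"
                 f"{profile.class_total('I'):.4f}\n")
        fh.write(f"{profile.sample_id}\tclassII_sum\t\t\t\t"
                 f"{profile.class_total('II'):.4f}\n")
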