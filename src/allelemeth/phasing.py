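"""Read-backed phasing: SNP calls with bisulfite masking, haplotype
assignment, per-allele methylation profiles and subject-level averaging.

Bisulfite chemistry makes some SNP alleles unreadable in one strand space:
in OT space a C allele is seen as C or T, in OB space a G allele as G or A.
When the conversion images of the two alleles overlap, the SNP is *masked*
for that read.  A read is assigned to a haplotype only when its unmasked
calls are consistent with exactly one catalogue haplotype; reads pooled per
assigned haplotype give per-allele methylation profiles, kept only at >= 5x
depth per haplotype (the study's floor).

Subject-level methylation averages the two alleles for heterozygotes.  At a
CpG-SNP, a T-carrying allele has no methylatable cytosine and contributes a
structural 0 (configurable to missing), which makes the subject-level
distribution at such a site near-bimodal by risk-allele count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignedRead
from .calling import ReadCallSet, call_read_cytosines, site_methylation
from .reference import AmpliconReference

__all__ = [
    "conversion_image",
    "genotype_read_snps",
    "assign_haplotype",
    "build_callset",
    "AlleleMethylationProfile",
    "SubjectMethylation",
    "build_allele_profiles",
    "subject_average",
    "subject_methylation_table",
]


def conversion_image(base: str, space: str) -> frozenset:
    """Possible read bases for a template base after bisulfite conversion."""
    if space == "OT" and base == "C":
        return frozenset("CT")
    if space == "OB" and base == "G":
        return frozenset("GA")
    return frozenset(base)


def genotype_read_snps(aligned: AlignedRead, reference: AmpliconReference) -> dict:
    """Call each SNP on one read, masking bisulfite-ambiguous alleles.

    Returns snp id -> allele base, "masked" (conversion images of the two
    alleles overlap in this read's space), or None (base matches neither
    image or position uncovered).
    """
    calls = {}
    for snp in reference.snps:
        img = [conversion_image(a, aligned.strand_space) for a in snp.alleles]
        if img[0] & img[1]:
            calls[snp.id] = "masked"
            continue
        base = aligned.read_base(snp.coord, reference.start)
        if base is None:
            calls[snp.id] = None
        elif base in img[0]:
            calls[snp.id] = snp.alleles[0]
        elif base in img[1]:
            calls[snp.id] = snp.alleles[1]
        else:
            calls[snp.id] = None
    return calls


def assign_haplotype(snp_calls: dict, reference: AmpliconReference) -> str | None:
    """Label from the haplotype catalogue consistent with the unmasked marker
    calls; None (unassigned) when zero or several haplotypes are consistent."""
    markers = reference.marker_snps
    informative = {
        i: snp_calls.get(s.id)
        for i, s in enumerate(markers)
        if snp_calls.get(s.id) not in (None, "masked")
    }
    if not informative:
        return None
    candidates = [
        h.label
        for h in reference.haplotypes
        if all(h.label[i] == b for i, b in informative.items())
    ]
    return candidates[0] if len(candidates) == 1 else None


def build_callset(
    aligned: AlignedRead, reference: AmpliconReference, subject_id: str | None = None
) -> ReadCallSet:
    """Genotype SNPs, assign the haplotype and call cytosines for one read."""
    snp_calls = genotype_read_snps(aligned, reference)
    return ReadCallSet(
        read_id=aligned.read_id,
        strand_space=aligned.strand_space,
        calls=call_read_cytosines(aligned, reference, snp_calls=snp_calls),
        snp_calls=snp_calls,
        haplotype=assign_haplotype(snp_calls, reference),
        subject_id=subject_id,
    )


@dataclass
class AlleleMethylationProfile:
    subject_id: str
    allele: str  # haplotype label
    sites: pd.DataFrame  # site, m_count, total, fraction
    depth: int  # reads assigned to this allele
    passes_depth: bool

    def fraction(self, site: str) -> float | None:
        hit = self.sites.loc[self.sites["site"] == site, "fraction"]
        return float(hit.iloc[0]) if len(hit) else None


def infer_diplotype(callsets, het_fraction: float = 0.2) -> tuple[str, str] | None:
    """Diplotype from read-label frequencies: the two most frequent labels
    when both hold >= ``het_fraction`` of assigned reads, else a homozygote
    of the most frequent."""
    labels = pd.Series([cs.haplotype for cs in callsets if cs.haplotype])
    if labels.empty:
        return None
    counts = labels.value_counts()
    top = counts.index[0]
    if len(counts) > 1 and counts.iloc[1] >= het_fraction * counts.sum():
        return tuple(sorted((top, counts.index[1])))
    return (top, top)


def build_allele_profiles(
    callsets,
    subject_id: str,
    reference: AmpliconReference,
    min_depth: int = 5,
    het_fraction: float = 0.2,
):
    """Pool one subject's reads per assigned haplotype.

    Returns (profiles, diplotype).  Profiles failing the per-haplotype depth
    floor are marked ``passes_depth=False`` (downstream statistics exclude
    them); an expected heterozygote with fewer than two passing alleles is
    flagged with a warning.
    """
    diplotype = infer_diplotype(callsets, het_fraction)
    if diplotype is None:
        warnings.warn(f"{subject_id}: no haplotype-assigned reads")
        return [], None
    profiles = []
    for label in dict.fromkeys(diplotype):  # unique, order-stable
        assigned = [cs for cs in callsets if cs.haplotype == label]
        depth = len(assigned)
        sites = (
            site_methylation(assigned, reference)
            if assigned
            else pd.DataFrame(columns=["site", "group", "m_count", "total", "fraction"])
        )
        profiles.append(
            AlleleMethylationProfile(
                subject_id=subject_id,
                allele=label,
                sites=sites,
                depth=depth,
                passes_depth=depth >= min_depth,
            )
        )
    if diplotype[0] != diplotype[1] and sum(p.passes_depth for p in profiles) < 2:
        warnings.warn(
            f"{subject_id}: heterozygote with <2 alleles passing the "
            f"{min_depth}x floor; averaging falls back to available allele(s)"
        )
    return profiles, diplotype


@dataclass
class SubjectMethylation:
    subject_id: str
    values: pd.Series  # site -> averaged DNAm in [0, 1]
    coverage: int  # total informative (haplotype-assigned, passing) reads
    diplotype: tuple | None = None


def subject_average(
    profiles,
    diplotype,
    reference: AmpliconReference,
    t_allele_zero: bool = True,
) -> SubjectMethylation:
    """Average per-site methylation across a subject's two alleles.

    Heterozygotes get the mean of the two allele fractions; homozygotes the
    single allele fraction.  At a CpG-SNP, a T-carrying allele contributes 0
    when ``t_allele_zero`` (structural absence of the cytosine), so C/T
    heterozygotes get half the C-allele fraction and T/T homozygotes 0;
    with ``t_allele_zero=False`` the T allele is treated as missing instead.
    """
    passing = {p.allele: p for p in profiles if p.passes_depth}
    if not passing:
        raise ValueError("no allele profile passes the depth floor")
    cpg_snp_sites = {s.short_name for s in reference.sites if s.is_cpg_snp}
    subject_id = profiles[0].subject_id
    values = {}
    for site in reference.sites:
        name = site.short_name
        per_allele = []
        for label in diplotype:
            prof = passing.get(label)
            if name in cpg_snp_sites:
                hap = reference.haplotype(label)
                if hap.linked_cpg_snp_allele != "C":
                    per_allele.append(0.0 if t_allele_zero else np.nan)
                    continue
            if prof is None:
                per_allele.append(np.nan)
                continue
            frac = prof.fraction(name)
            per_allele.append(np.nan if frac is None else frac)
        arr = np.asarray(per_allele, dtype=float)
        if np.isnan(arr).all():
            values[name] = np.nan
        else:
            values[name] = float(np.nanmean(arr))
    coverage = sum(p.depth for p in passing.values())
    return SubjectMethylation(
        subject_id=subject_id,
        values=pd.Series(values),
        coverage=coverage,
        diplotype=tuple(diplotype),
    )


def subject_methylation_table(subject_meths) -> pd.DataFrame:
    """One row per subject, one column per site, plus coverage."""
    rows = {}
    cov = {}
    for sm in subject_meths:
        rows[sm.subject_id] = sm.values
        cov[sm.subject_id] = sm.coverage
    table = pd.DataFrame(rows).T
    table["coverage"] = pd.Series(cov)
    table.index.name = "subject_id"
    return table
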