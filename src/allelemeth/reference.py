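"""Amplicon coordinate system: cytosine sites, SNPs and the haplotype catalogue.

The analysis is anchored to a single PCR amplicon.  All genomic coordinates
are 1-based inclusive (the convention of the locus coordinates the study
reports); BED export converts to 0-based half-open.  Only plus-strand
cytosines are enumerated: each ``C`` in the plus-strand reference is a
potential methylation site, classified ``CpG`` when the next base is ``G``
and ``CpH`` otherwise.  A C>T polymorphism that destroys a CpG (a "CpG-SNP")
is represented as a CpG site carrying ``is_cpg_snp`` plus a linked
:class:`SnpSite`; methylation at such a site exists only on C-carrying
alleles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from Bio import SeqIO

__all__ = [
    "AnnotationError",
    "ReferenceMismatchError",
    "CytosineSite",
    "SnpSite",
    "HaplotypeDef",
    "AmpliconReference",
    "enumerate_cytosines",
    "build_reference",
    "load_annotation",
    "load_reference",
]


class AnnotationError(ValueError):
    """Annotation inconsistent with itself or with the sequence coordinates."""


class ReferenceMismatchError(ValueError):
    """A declared SNP allele does not match the reference base."""


@dataclass(frozen=True)
class SnpSite:
    id: str
    coord: int  # 1-based genomic coordinate
    alleles: tuple[str, str]  # plus-strand bases
    role: str = "haplotype_marker"  # or "cpg_snp"

    def __post_init__(self):
        if self.alleles[0] == self.alleles[1]:
            raise AnnotationError(f"SNP {self.id}: alleles must be distinct")
        if self.role not in ("haplotype_marker", "cpg_snp"):
            raise AnnotationError(f"SNP {self.id}: unknown role {self.role!r}")


@dataclass(frozen=True)
class CytosineSite:
    coord: int
    context: str  # "CpG" | "CpH"
    short_name: str
    is_cpg_snp: bool = False
    snp_id: str | None = None


@dataclass(frozen=True)
class HaplotypeDef:
    label: str  # ordered allele string over the haplotype markers, e.g. "TGT"
    is_risk: bool = False
    linked_cpg_snp_allele: str | None = None  # base carried at the CpG-SNP


def _short_names(coords, contexts):
    """Name sites context + '_' + last four digits of the coordinate.

    Collisions (two coordinates sharing their last four digits) are resolved
    by appending the full coordinate, which restores uniqueness.
    """
    names = [f"{ctx}_{str(c)[-4:]}" for c, ctx in zip(coords, contexts)]
    seen: dict[str, int] = {}
    for n in names:
        seen[n] = seen.get(n, 0) + 1
    return [
        n if seen[n] == 1 else f"{n}_{c}" for n, c in zip(names, coords)
    ]


def enumerate_cytosines(seq: str, start: int) -> list[CytosineSite]:
    """Scan the plus strand for cytosines and classify their context.

    Every ``C`` yields a site; context is ``CpG`` when followed by ``G``,
    ``CpH`` otherwise (a terminal ``C`` has no next base and is CpH).
    """
    coords, contexts = [], []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        nxt = seq[i + 1] if i + 1 < len(seq) else ""
        coords.append(start + i)
        contexts.append("CpG" if nxt == "G" else "CpH")
    names = _short_names(coords, contexts)
    return [
        CytosineSite(coord=c, context=ctx, short_name=n)
        for c, ctx, n in zip(coords, contexts, names)
    ]


@dataclass
class AmpliconReference:
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    seq: str  # plus strand, A/C/G/T
    sites: list[CytosineSite] = field(default_factory=list)
    snps: list[SnpSite] = field(default_factory=list)
    haplotypes: list[HaplotypeDef] = field(default_factory=list)

    # -- basic accessors ---------------------------------------------------
    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def marker_snps(self) -> list[SnpSite]:
        return [s for s in self.snps if s.role == "haplotype_marker"]

    @property
    def cpg_snps(self) -> list[SnpSite]:
        return [s for s in self.snps if s.role == "cpg_snp"]

    @property
    def haplotype_labels(self) -> list[str]:
        return [h.label for h in self.haplotypes]

    @property
    def risk_haplotype(self) -> str | None:
        for h in self.haplotypes:
            if h.is_risk:
                return h.label
        return None

    def base_at(self, coord: int) -> str:
        return self.seq[coord - self.start]

    def site_by_name(self, short_name: str) -> CytosineSite:
        for s in self.sites:
            if s.short_name == short_name:
                return s
        raise KeyError(short_name)

    def haplotype(self, label: str) -> HaplotypeDef:
        for h in self.haplotypes:
            if h.label == label:
                return h
        raise KeyError(label)

    def allele_seq(self, label: str) -> str:
        """Plus-strand sequence of one allele: reference with the haplotype's
        marker bases and its linked CpG-SNP base substituted in."""
        hap = self.haplotype(label)
        seq = list(self.seq)
        for snp, base in zip(self.marker_snps, hap.label):
            if base not in snp.alleles:
                raise AnnotationError(
                    f"haplotype {label}: base {base} not an allele of {snp.id}"
                )
            seq[snp.coord - self.start] = base
        if hap.linked_cpg_snp_allele is not None:
            for snp in self.cpg_snps:
                seq[snp.coord - self.start] = hap.linked_cpg_snp_allele
        return "".join(seq)

    # -- export ------------------------------------------------------------
    def sites_to_bed(self, path) -> None:
        """Write cytosine sites as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for s in self.sites:
                fh.write(f"{self.chrom}\t{s.coord - 1}\t{s.coord}\t{s.short_name}\n")


def build_reference(fasta_record, annotation: dict) -> AmpliconReference:
    """Assemble an :class:`AmpliconReference` from a FASTA record and an
    annotation dict (start/end/chrom, snps[], haplotypes[]).

    Validates SNP coordinates against the sequence: the reference base must
    equal one of the two declared alleles.
    """
    seq = str(getattr(fasta_record, "seq", fasta_record)).upper()
    if not seq or set(seq) - set("ACGT"):
        raise AnnotationError("sequence must be non-empty and contain only A/C/G/T")
    start = int(annotation["start"])
    end = int(annotation.get("end", start + len(seq) - 1))
    if end - start + 1 != len(seq):
        raise AnnotationError(
            f"coordinates span {end - start + 1} bases but sequence has {len(seq)}"
        )
    snps = [
        SnpSite(
            id=s["id"],
            coord=int(s["coord"]),
            alleles=tuple(s["alleles"]),
            role=s.get("role", "haplotype_marker"),
        )
        for s in annotation.get("snps", [])
    ]
    coords = [s.coord for s in snps]
    if len(set(coords)) != len(coords):
        raise AnnotationError("duplicate SNP coordinates")
    for s in snps:
        if not (start <= s.coord <= end):
            raise AnnotationError(f"SNP {s.id} at {s.coord} outside [{start}, {end}]")
        ref_base = seq[s.coord - start]
        if ref_base not in s.alleles:
            raise ReferenceMismatchError(
                f"SNP {s.id}: reference base {ref_base} not among alleles {s.alleles}"
            )
    markers = [s for s in snps if s.role == "haplotype_marker"]
    haps = [
        HaplotypeDef(
            label=h["label"],
            is_risk=bool(h.get("is_risk", False)),
            linked_cpg_snp_allele=h.get("cpg_snp_allele"),
        )
        for h in annotation.get("haplotypes", [])
    ]
    labels = [h.label for h in haps]
    if len(set(labels)) != len(labels):
        raise AnnotationError("duplicate haplotype labels")
    for h in haps:
        if len(h.label) != len(markers):
            raise AnnotationError(
                f"haplotype {h.label}: length != number of marker SNPs ({len(markers)})"
            )

    sites = enumerate_cytosines(seq, start)
    cpg_snp_by_coord = {s.coord: s for s in snps if s.role == "cpg_snp"}
    out_sites = []
    for site in sites:
        snp = cpg_snp_by_coord.get(site.coord)
        if snp is not None:
            # CpG-SNP naming follows the site's role, not the raw context scan
            name = site.short_name.replace("CpG_", "CpG-SNP_")
            site = replace(site, is_cpg_snp=True, snp_id=snp.id, short_name=name)
        out_sites.append(site)

    return AmpliconReference(
        name=annotation.get("name", getattr(fasta_record, "id", "amplicon")),
        chrom=annotation.get("chrom", "chr?"),
        start=start,
        end=end,
        seq=seq,
        sites=out_sites,
        snps=snps,
        haplotypes=haps,
    )


def load_annotation(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_reference(fasta_path, annotation_path) -> AmpliconReference:
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    return build_reference(record, load_annotation(annotation_path))
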