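"""Per-read cytosine calls and per-site methylation fractions.

A methylation call at a cytosine site is M (unconverted, read base C in OT
space / G at the partner position in OB space), U (converted, T / A), or NA.
Bases that are neither the methylated nor the converted form (sequencing
errors) are NA, not U, so errors do not deflate methylation.  A site's
methylation fraction is #M / (#M + #U); NA calls never enter the denominator.
CpH sites are expected unmethylated in blood and provide the
bisulfite-conversion-efficiency control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignedRead
from .reference import AmpliconReference

__all__ = [
    "M", "U", "NA",
    "ReadCallSet",
    "SiteMethylation",
    "call_read_cytosines",
    "site_methylation",
    "conversion_qc",
    "ConversionQC",
]

M, U, NA = np.int8(1), np.int8(0), np.int8(-1)

_B = {b: np.uint8(ord(b)) for b in "ACGT"}
_ARRAY_CACHE: dict[int, dict] = {}


def _site_arrays(reference: AmpliconReference) -> dict:
    key = id(reference)
    if key not in _ARRAY_CACHE:
        sites = reference.sites
        offs = np.array([s.coord - reference.start for s in sites], dtype=np.int64)
        is_cpg = np.array([s.context == "CpG" for s in sites])
        is_snp = np.array([s.is_cpg_snp for s in sites])
        snp_ids = [s.snp_id for s in sites]
        _ARRAY_CACHE[key] = {
            "offsets": offs, "is_cpg": is_cpg, "is_cpg_snp": is_snp,
            "snp_ids": snp_ids,
            "names": [s.short_name for s in sites],
        }
    return _ARRAY_CACHE[key]


@dataclass
class ReadCallSet:
    read_id: str
    strand_space: str
    calls: np.ndarray  # int8 per reference site: 1=M, 0=U, -1=NA
    snp_calls: dict = field(default_factory=dict)  # snp id -> base | "masked" | None
    haplotype: str | None = None
    subject_id: str | None = None


def call_read_cytosines(
    aligned: AlignedRead,
    reference: AmpliconReference,
    snp_calls: dict | None = None,
) -> np.ndarray:
    """Methylation call per reference cytosine site for one aligned read.

    OT reads inform every plus-strand cytosine directly; OB reads inform CpG
    sites through the G partner at coord+1 (plus-strand CpH sites have no
    informative partner in OB space and are NA).  CpG-SNP sites are called
    only when the read's SNP call is the C allele — on OT reads the C/T SNP
    is conversion-masked, so such sites are NA there.
    """
    arr = _site_arrays(reference)
    seq = np.frombuffer(aligned.seq.encode(), dtype=np.uint8)
    n_sites = len(arr["offsets"])
    calls = np.full(n_sites, NA, dtype=np.int8)

    if aligned.strand_space == "OT":
        target = arr["offsets"]
        informative = np.ones(n_sites, dtype=bool)
        meth_base, conv_base = _B["C"], _B["T"]
    else:
        target = arr["offsets"] + 1
        informative = arr["is_cpg"].copy()
        meth_base, conv_base = _B["G"], _B["A"]
    in_range = target < reference.length
    informative &= in_range
    idx = aligned.ref_to_read[np.clip(target, 0, reference.length - 1)]
    covered = informative & (idx >= 0)
    bases = seq[np.clip(idx, 0, len(seq) - 1)]
    calls[covered & (bases == meth_base)] = M
    calls[covered & (bases == conv_base)] = U

    # CpG-SNP gating
    snp_mask = arr["is_cpg_snp"]
    if snp_mask.any():
        if aligned.strand_space == "OT":
            calls[snp_mask] = NA  # C/T conversion-masked in OT space
        else:
            for i in np.nonzero(snp_mask)[0]:
                call = (snp_calls or {}).get(arr["snp_ids"][i])
                if call != "C":
                    calls[i] = NA
    return calls


@dataclass
class SiteMethylation:
    site: str
    group: object
    m_count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.m_count / self.total


def site_methylation(
    callsets, reference: AmpliconReference, group_fn=None
) -> pd.DataFrame:
    """Per-site methylation fractions, optionally per group.

    ``group_fn(callset)`` maps each read to a grouping key (subject, allele,
    ...); default pools everything.  Sites with zero informative reads in a
    group are omitted.  Returns a tidy frame (site, group, m_count, total,
    fraction).
    """
    if not callsets:
        raise ValueError("need at least one callset")
    arr = _site_arrays(reference)
    names = arr["names"]
    groups: dict[object, list[np.ndarray]] = {}
    for cs in callsets:
        key = group_fn(cs) if group_fn else "all"
        groups.setdefault(key, []).append(cs.calls)
    rows = []
    for key, stacks in groups.items():
        mat = np.stack(stacks)
        m = (mat == M).sum(axis=0)
        u = (mat == U).sum(axis=0)
        total = m + u
        for i, name in enumerate(names):
            if total[i] == 0:
                continue
            rows.append(
                {"site": name, "group": key, "m_count": int(m[i]),
                 "total": int(total[i]), "fraction": m[i] / total[i]}
            )
    return pd.DataFrame(rows)


@dataclass
class ConversionQC:
    efficiency: float | None
    n_informative: int
    cph_report: pd.DataFrame
    flagged: list[str]
    indeterminate: bool


def conversion_qc(
    callsets, reference: AmpliconReference, flag_threshold: float = 0.2
) -> ConversionQC:
    """Estimate bisulfite conversion efficiency from CpH sites.

    efficiency = 1 - pooled CpH methylation fraction.  Any CpH site whose own
    fraction exceeds ``flag_threshold`` (i.e. is not hypomethylated) is
    flagged.  No CpH coverage at all -> QC is indeterminate.
    """
    arr = _site_arrays(reference)
    cph = ~arr["is_cpg"]
    if not cph.any() or not callsets:
        return ConversionQC(None, 0, pd.DataFrame(), [], True)
    mat = np.stack([cs.calls for cs in callsets])[:, cph]
    m = (mat == M).sum(axis=0)
    u = (mat == U).sum(axis=0)
    total = m + u
    pooled = total.sum()
    if pooled == 0:
        return ConversionQC(None, 0, pd.DataFrame(), [], True)
    names = [n for n, c in zip(arr["names"], cph) if c]
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, m / np.maximum(total, 1), np.nan)
    report = pd.DataFrame({"site": names, "m_count": m, "total": total,
                           "fraction": frac})
    flagged = [n for n, f, t in zip(names, frac, total)
               if t > 0 and f > flag_threshold]
    if flagged:
        warnings.warn(f"CpH sites not hypomethylated: {flagged}")
    return ConversionQC(
        efficiency=1.0 - m.sum() / pooled,
        n_informative=int(pooled),
        cph_report=report,
        flagged=flagged,
        indeterminate=False,
    )
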