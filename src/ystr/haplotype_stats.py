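"""Allele/haplotype frequencies and forensic parameters.

All estimates are plain counting estimates over the samples with valid
data.  Gene diversity (GD) and haplotype diversity (HD) use the
unbiased form

    GD = n/(n-1) * (1 - sum_i p_i^2)

with *n* the number of observations and *p_i* the allele (or haplotype)
frequencies.  Discrimination capacity is DC = N_diff / n, and the
fraction of unique haplotypes F_UH = N_unique / N_diff, where N_diff is
the number of different haplotypes and N_unique those seen exactly once.

Multi-copy markers are handled as unordered allele combinations: a
genotype {13, 16} hashes identically regardless of entry order, and
allele frequencies can be computed either per combination
(``mode="combined"``) or over the pooled individual alleles
(``mode="separated"``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_qc import Genotype, HaplotypeDataset
from .locus_registry import PanelSpec, Registry

__all__ = [
    "FrequencyTable",
    "HaplotypeSummary",
    "allele_frequencies",
    "gene_diversity",
    "haplotype_summary",
    "summary_from_spectrum",
    "shared_haplotype_report",
]


@dataclass(frozen=True)
class FrequencyTable:
    """Allele (or allele-combination) counts and frequencies at one locus."""

    locus: str
    counts: Mapping[object, int]  # allele or sorted allele tuple -> count
    n_effective: int  # total observations (samples, or alleles if separated)

    @property
    def frequencies(self) -> dict[object, float]:
        return {a: c / self.n_effective for a, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.locus, _label(a), c, c / self.n_effective)
            for a, c in sorted(self.counts.items(), key=lambda kv: _sort_key(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "count", "frequency"])


def _label(allele) -> str:
    if isinstance(allele, tuple):
        return "-".join(str(a) for a in allele)
    return str(allele)


def _sort_key(allele):
    return allele if isinstance(allele, tuple) else (allele,)


class UndefinedDiversityError(ValueError):
    pass


def allele_frequencies(
    ds: HaplotypeDataset, locus: str, mode: str = "combined"
) -> FrequencyTable:
    """Count allele frequencies at one locus by mere counting.

    ``mode="combined"`` treats a multi-copy genotype as one unordered
    combination; ``mode="separated"`` pools the individual alleles (each
    sample then contributes copy_number observations).  For single-copy
    loci the two modes coincide.
    """
    if mode not in {"combined", "separated"}:
        raise ValueError(f"mode must be 'combined' or 'separated', got {mode!r}")
    if locus not in ds.loci:
        raise KeyError(f"locus {locus!r} not present in dataset")
    counts: Counter = Counter()
    n = 0
    for sample in ds.samples:
        g = ds.genotype(sample, locus)
        if g is None:
            continue
        if mode == "separated":
            counts.update(g)
            n += len(g)
        else:
            counts[g if len(g) > 1 else g[0]] += 1
            n += 1
    return FrequencyTable(locus=locus, counts=dict(counts), n_effective=n)


def gene_diversity(ft: FrequencyTable) -> float:
    """Unbiased gene diversity n/(n-1) (1 - sum p_i^2)."""
    n = ft.n_effective
    if n < 2:
        raise UndefinedDiversityError(
            f"{ft.locus}: gene diversity undefined for n={n}"
        )
    ss = sum((c / n) ** 2 for c in ft.counts.values())
    return n / (n - 1) * (1.0 - ss)


@dataclass(frozen=True)
class HaplotypeSummary:
    """Population haplotype statistics over one panel."""

    panel: str
    n: int  # usable samples
    n_excluded: int  # samples dropped for missing data at a panel locus
    n_diff: int
    n_unique: int
    sharing_spectrum: Mapping[int, int]  # multiplicity -> number of haplotypes
    f_uh: float | None  # None when fewer than 2 different haplotypes
    hd: float
    dc: float
    locus_gd: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n", self.n),
            ("n_excluded", self.n_excluded),
            ("N_diff", self.n_diff),
            ("N_unique", self.n_unique),
            ("F_UH", "NA" if self.f_uh is None else round(self.f_uh, 6)),
            ("HD", round(self.hd, 9)),
            ("DC", round(self.dc, 6)),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value"])


def _panel_haplotype(ds: HaplotypeDataset, sample: str, loci) -> tuple | None:
    parts = []
    for locus in loci:
        g = ds.genotype(sample, locus)
        if g is None:
            return None
        parts.append(g)  # genotypes are stored sorted, so order-invariant
    return tuple(parts)


def summary_from_spectrum(
    spectrum: Mapping[int, int], panel: str = "", locus_gd: Mapping[str, float] = ()
) -> HaplotypeSummary:
    """Forensic parameters from a sharing spectrum (multiplicity -> count).

    Useful when only the haplotype multiplicity distribution is known,
    e.g. a published table of shared-haplotype counts.
    """
    spectrum = {int(m): int(c) for m, c in spectrum.items() if c}
    n = sum(m * c for m, c in spectrum.items())
    n_diff = sum(spectrum.values())
    n_unique = spectrum.get(1, 0)
    if n < 2:
        raise UndefinedDiversityError("need at least 2 samples")
    ss = sum(c * (m / n) ** 2 for m, c in spectrum.items())
    hd = n / (n - 1) * (1.0 - ss)
    return HaplotypeSummary(
        panel=panel,
        n=n,
        n_excluded=0,
        n_diff=n_diff,
        n_unique=n_unique,
        sharing_spectrum=spectrum,
        f_uh=(n_unique / n_diff) if n_diff >= 2 else None,
        hd=hd,
        dc=n_diff / n,
        locus_gd=dict(locus_gd),
    )


def haplotype_summary(
    ds: HaplotypeDataset, panel: PanelSpec, registry: Registry | None = None
) -> HaplotypeSummary:
    """Haplotype counts, sharing spectrum and forensic parameters.

    A haplotype is the ordered tuple of genotypes over the panel loci
    (multi-copy genotypes as ascending pairs).  Samples missing any
    panel locus are excluded and counted in ``n_excluded``.
    """
    if not panel.loci:
        raise ValueError("empty panel")
    usable = ds.complete_samples(panel.loci)
    if len(usable) < 2:
        raise UndefinedDiversityError(
            f"panel {panel.name}: only {len(usable)} usable sample(s)"
        )
    haps = Counter(_panel_haplotype(ds, s, panel.loci) for s in usable)
    spectrum = Counter(haps.values())
    locus_gd = {}
    for locus in panel.loci:
        try:
            locus_gd[locus] = gene_diversity(allele_frequencies(ds, locus))
        except UndefinedDiversityError:
            pass
    base = summary_from_spectrum(spectrum, panel=panel.name, locus_gd=locus_gd)
    return HaplotypeSummary(
        panel=panel.name,
        n=base.n,
        n_excluded=len(ds.samples) - len(usable),
        n_diff=base.n_diff,
        n_unique=base.n_unique,
        sharing_spectrum=base.sharing_spectrum,
        f_uh=base.f_uh,
        hd=base.hd,
        dc=base.dc,
        locus_gd=locus_gd,
    )


def shared_haplotype_report(ds: HaplotypeDataset, panel: PanelSpec) -> pd.DataFrame:
    """Haplotypes carried by two or more samples, with their members.

    Ordered by multiplicity (descending) then lexicographic haplotype,
    so the output is deterministic for a given dataset.
    """
    if not panel.loci:
        raise ValueError("empty panel")
    usable = ds.complete_samples(panel.loci)
    groups: dict[tuple, list[str]] = {}
    for s in usable:
        groups.setdefault(_panel_haplotype(ds, s, panel.loci), []).append(s)
    shared = [(h, members) for h, members in groups.items() if len(members) >= 2]
    shared.sort(key=lambda hm: (-len(hm[1]), hm[0]))
    rows = []
    for i, (hap, members) in enumerate(shared, 1):
        label = " ".join(
            ",".join(str(a) for a in g) for g in hap
        )
        rows.append((f"H{i:05d}", label, len(members), ";".join(sorted(members))))
    return pd.DataFrame(
        rows, columns=["haplotype_id", "haplotype", "multiplicity", "samples"]
    )
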