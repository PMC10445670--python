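"""Shipped reference tables from the Northern Han Chinese cohort study.

These are the published *summary* numbers — per-locus mutation counts,
panel-wise haplotype sharing spectra, the novel repeat-region variant
structures, and cohort-level figures — not the underlying genotypes,
which are not redistributed.  They serve as worked-example inputs and
as the defaults for the cohort-like simulation profile.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from io import StringIO

import pandas as pd
import yaml

__all__ = [
    "load_mutation_counts",
    "load_sharing_spectra",
    "load_novel_variants",
    "load_cohort_summary",
]


def _text(name: str) -> str:
    return (resources.files("ystr.data") / name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def load_mutation_counts() -> pd.DataFrame:
    """Per-locus transfers, mutations, step and direction counts."""
    return pd.read_csv(StringIO(_text("han_mutation_counts.csv")))


@lru_cache(maxsize=None)
def load_sharing_spectra() -> dict[str, dict[int, int]]:
    """Panel -> {haplotype multiplicity -> number of haplotypes}."""
    df = pd.read_csv(StringIO(_text("han_sharing_spectra.csv")))
    out: dict[str, dict[int, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.panel, {})[int(row.multiplicity)] = int(row.n_haplotypes)
    return out


@lru_cache(maxsize=None)
def load_novel_variants() -> pd.DataFrame:
    """Novel repeat-region variant alleles: locus, designation, structure."""
    return pd.read_csv(
        StringIO(_text("novel_repeat_variants.tsv")), sep="\t", dtype=str
    )


@lru_cache(maxsize=None)
def load_cohort_summary() -> dict:
    """Cohort-level figures (pair count, mutated-locus histogram, ages)."""
    return yaml.safe_load(_text("han_cohort.yaml"))
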