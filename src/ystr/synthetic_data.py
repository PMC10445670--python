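"""Synthetic Y-STR populations and father-son pairs with known truth.

The generator draws father haplotypes locus-by-locus from configurable
allele spectra and transmits them to sons under a stepwise mutation
process: each allele transfer mutates with the locus rate mu, the step
size is 1/2/3+ with a geometric tail, and the direction is a gain with
a configurable probability.  Optionally the per-transfer rate is
modulated log-linearly by the father's age at gametogenesis, which is
drawn from a truncated normal.

The default profile is "cohort-like": per-locus rates equal to the
published counts of the 2 548-pair Northern Han Chinese study
(mutations/transfers from the shipped counts table), step-size split
344:8:4 (one/two/multi-step), near-balanced gain/loss (173:183), and
father ages ~N(26.29, 4.21^2) truncated to 15..55.  Allele spectra are
discretized normals around each locus's typical allele — illustrative
of real spectra, not a reconstruction of the cohort.

Everything is driven by one integer seed; a fixed seed reproduces the
output bit for bit.  The DYS389 pair is simulated coherently: DYS389I
and the II-minus-I stretch mutate independently and the reported
DYS389II allele is their sum, so the nested structure always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_qc import Allele, Genotype, HaplotypeDataset, PairRecord
from .locus_registry import Registry, default_registry
from .refdata import load_mutation_counts

__all__ = [
    "StepDistribution",
    "SimulationConfig",
    "cohort_like_config",
    "simulate_population",
    "simulate_pairs",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class StepDistribution:
    """P(step=1), P(step=2), and a geometric tail for step >= 3."""

    p1: float = 344 / 356
    p2: float = 8 / 356
    tail_continue: float = 0.5  # P(step k+1 | step >= k) within the tail

    def __post_init__(self):
        p3 = 1.0 - self.p1 - self.p2
        if min(self.p1, self.p2, p3) < -1e-12:
            raise ValueError("step probabilities must be non-negative and sum <= 1")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.random(size)
        steps = np.where(u < self.p1, 1, np.where(u < self.p1 + self.p2, 2, 3))
        tail = steps == 3
        if tail.any():
            steps[tail] += rng.geometric(1.0 - self.tail_continue, tail.sum()) - 1
        return steps


@dataclass
class SimulationConfig:
    registry: Registry
    spectra: Mapping[str, Mapping[int, float]]  # locus -> repeat number -> prob
    mu: Mapping[str, float]  # locus -> per-transfer mutation rate
    step_dist: StepDistribution = field(default_factory=StepDistribution)
    gain_prob: float = 173 / 356
    age_mean: float = 26.29
    age_sd: float = 4.21
    age_range: tuple[float, float] = (15.0, 55.0)
    age_effect: float = 0.0  # log-linear coefficient on mu per year above mean
    n_pairs: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for locus, spectrum in self.spectra.items():
            total = sum(spectrum.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{locus}: spectrum sums to {total}, not 1")
            if any(p < 0 for p in spectrum.values()):
                raise ValueError(f"{locus}: negative probability")
        for locus, m in self.mu.items():
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"{locus}: mu={m} outside [0, 1]")


def _discrete_normal(center: int, sd: float, half_width: int = 4) -> dict[int, float]:
    lo = max(1, center - half_width)
    alleles = np.arange(lo, center + half_width + 1)
    w = np.exp(-0.5 * ((alleles - center) / sd) ** 2)
    w /= w.sum()
    return {int(a): float(p) for a, p in zip(alleles, w)}


def cohort_like_config(
    n_pairs: int = 2548,
    seed: int = 0,
    registry: Registry | None = None,
    spectrum_sd: float = 1.2,
) -> SimulationConfig:
    """The default profile: published per-locus rates, realistic spectra."""
    registry = registry or default_registry()
    counts = load_mutation_counts().set_index("locus")
    mu, spectra = {}, {}
    for spec in registry:
        row = counts.loc[spec.name]
        mu[spec.name] = float(row["mutations"] / row["transfers"])
        center = spec.typical_allele or 15
        if spec.name == "DYS389II":
            # simulate the II-specific stretch; reported II = I + stretch
            center = center - registry.get_locus("DYS389I").typical_allele
        spectra[spec.name] = _discrete_normal(center, spectrum_sd)
    return SimulationConfig(
        registry=registry, spectra=spectra, mu=mu, n_pairs=n_pairs, seed=seed
    )


def _draw_alleles(
    spectrum: Mapping[int, float], rng: np.random.Generator, size: int
) -> np.ndarray:
    alleles = np.array(sorted(spectrum))
    probs = np.array([spectrum[a] for a in alleles])
    return rng.choice(alleles, size=size, p=probs / probs.sum())


def simulate_population(cfg: SimulationConfig) -> HaplotypeDataset:
    """Draw an i.i.d. male population from the configured allele spectra."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    samples = tuple(f"S{i + 1:05d}" for i in range(n))
    alleles: dict[tuple[str, str], Genotype] = {}
    father_mats = _draw_population_matrix(cfg, rng, n)
    for locus, mat in father_mats.items():
        for i, sample in enumerate(samples):
            alleles[(sample, locus)] = tuple(
                sorted(Allele(int(v) * 10) for v in mat[i])
            )
    return HaplotypeDataset(
        samples=samples, loci=tuple(father_mats), alleles=alleles
    )


def _draw_population_matrix(
    cfg: SimulationConfig, rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    """Father repeat numbers per locus, shape (n, copy_number).

    DYS389II is drawn as the II-minus-I stretch and reported as I + stretch.
    """
    out: dict[str, np.ndarray] = {}
    stretch = None
    for spec in cfg.registry:
        mat = np.column_stack(
            [
                _draw_alleles(cfg.spectra[spec.name], rng, n)
                for _ in range(spec.copy_number)
            ]
        )
        out[spec.name] = mat
        if spec.name == "DYS389II":
            stretch = mat
    if stretch is not None and "DYS389I" in out:
        out["DYS389II"] = out["DYS389I"] + stretch
    return out


def simulate_pairs(cfg: SimulationConfig) -> tuple[list[PairRecord], pd.DataFrame]:
    """Simulate father-son pairs; returns pairs plus the true event log.

    The event log has one row per mutated allele copy with the locus,
    pedigree id, copy index, father/son repeat numbers, step and
    direction — the ground truth against which detection can be checked.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    ids = [f"P{i + 1:05d}" for i in range(n)]

    a, b = (cfg.age_range[0] - cfg.age_mean) / cfg.age_sd, (
        cfg.age_range[1] - cfg.age_mean
    ) / cfg.age_sd
    from scipy.stats import truncnorm

    ages = truncnorm.rvs(
        a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng
    )
    age_factor = (
        np.exp(cfg.age_effect * (ages - cfg.age_mean)) if cfg.age_effect else np.ones(n)
    )

    # fathers: per-locus matrices of repeat numbers (DYS389II already nested)
    father = _draw_population_matrix(cfg, rng, n)
    # the mutation process acts on DYS389I and the II stretch separately
    stretch = father["DYS389II"] - father["DYS389I"] if "DYS389II" in father else None

    son: dict[str, np.ndarray] = {}
    log_rows = []
    for spec in cfg.registry:
        locus = spec.name
        base = (
            stretch
            if locus == "DYS389II" and stretch is not None
            else father[locus]
        )
        son_mat = base.copy()
        for copy in range(spec.copy_number):
            p = np.clip(cfg.mu[locus] * age_factor, 0.0, 1.0)
            mutated = np.nonzero(rng.random(n) < p)[0]
            if mutated.size:
                steps = cfg.step_dist.draw(rng, mutated.size)
                sign = np.where(rng.random(mutated.size) < cfg.gain_prob, 1, -1)
                delta = steps * sign
                # reflect at 1 repeat: alleles must stay positive
                new = np.maximum(base[mutated, copy] + delta, 1)
                delta = new - base[mutated, copy]
                son_mat[mutated, copy] = new
                for i, d in zip(mutated, delta):
                    if d == 0:
                        continue
                    log_rows.append(
                        (
                            ids[i],
                            locus,
                            copy,
                            int(base[i, copy]),
                            int(son_mat[i, copy]),
                            int(abs(d)),
                            "gain" if d > 0 else "loss",
                        )
                    )
        son[locus] = son_mat
    if stretch is not None:
        son["DYS389II"] = son["DYS389I"] + son["DYS389II"]
        # log entries for the stretch already carry stretch-scale alleles,
        # matching the subtracted (II - I) scoring convention

    pairs = []
    for i, ped in enumerate(ids):
        f_g = {
            locus: tuple(sorted(Allele(int(v) * 10) for v in father[locus][i]))
            for locus in father
        }
        s_g = {
            locus: tuple(sorted(Allele(int(v) * 10) for v in son[locus][i]))
            for locus in son
        }
        pairs.append(
            PairRecord(
                pedigree_id=ped, father=f_g, son=s_g, father_age=float(round(ages[i]))
            )
        )
    log = pd.DataFrame(
        log_rows,
        columns=[
            "pedigree_id",
            "locus",
            "copy",
            "father_allele",
            "son_allele",
            "step",
            "direction",
        ],
    )
    return pairs, log


def pairs_to_frame(pairs: Sequence[PairRecord], registry: Registry) -> pd.DataFrame:
    """Render pairs as a pedigree table in the two-rows-per-pair dialect."""
    loci = [s.name for s in registry]
    rows = []
    for pair in pairs:
        for role, genos in (("P", pair.father), ("O", pair.son)):
            row = {"PedigreeID": pair.pedigree_id, "Role": role}
            if pair.father_age is not None:
                base = 1980 if role == "P" else 1980 + pair.father_age
                row["BirthYear"] = int(base)
            for locus in loci:
                g = genos.get(locus)
                row[locus] = ",".join(str(a) for a in g) if g else ""
            rows.append(row)
    return pd.DataFrame(rows)
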