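"""Synthetic-data generators for the whole pipeline.

Every input the analysis consumes can be generated here with the
statistical structure the downstream methods assume:

* diet-grid pupariation assays from a per-genotype diet-response model
  (logistic survival, log-normal pupariation time);
* two diverged parental genomes as genotype tables with fixed
  interspecies differences plus within-species polymorphism;
* pairwise coding-sequence alignments with exact, controlled counts of
  amino-acid-changing and silent substitutions, and neutrally evolved
  pairs for Ka/Ks calibration.

All randomness flows from one explicit integer seed through a named
:class:`numpy.random.Generator`; identical (spec, seed) gives identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .nutrient_space import GRID_ASSAY_COLUMNS, GridAssay
from .seqdiv import CODON_TO_AA, STOP_CODONS, _BASES

__all__ = [
    "GenotypeDietModel",
    "ParentalGenomeSpec",
    "CodingPairSpec",
    "DEFAULT_DIET_GRID",
    "DEFAULT_OBS_TIMES",
    "tolerant_model",
    "intolerant_model",
    "simulate_grid_assay",
    "simulate_parental_genomes",
    "simulate_coding_pair",
    "simulate_neutral_coding_pair",
    "write_genotype_table",
    "write_fasta_pair",
]

#: the 5 x 5 yeast x sucrose grid (% w/v) used in the diet assays.
DEFAULT_DIET_GRID = tuple(
    (y, s) for y in (1.25, 2.5, 5.0, 10.0, 20.0) for s in (0.0, 5.0, 10.0, 15.0, 20.0)
)

#: pupariation scored every 24 h for 408 h.
DEFAULT_OBS_TIMES = tuple(range(24, 409, 24))

_SENSE_CODONS = sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)


@dataclass(frozen=True)
class GenotypeDietModel:
    """Diet response of one genotype.

    Median development time (hours) is linear in the diet:
    ``t = clip(t_base + t_sucrose_slope * sucrose% + t_yeast_slope * yeast%)``,
    with log-normal dispersion ``sigma_log`` (log-scale sd) around it.
    Survival of each larva is an independent Bernoulli with logistic
    probability ``expit(surv_intercept + surv_sucrose_slope * sucrose% +
    surv_yeast_slope * yeast%)``.
    """

    name: str
    t_base: float  # hours
    t_sucrose_slope: float  # hours per % sucrose (positive = sugar delays)
    t_yeast_slope: float  # hours per % yeast (negative = yeast speeds up)
    surv_intercept: float
    surv_sucrose_slope: float  # on the logit scale, per % sucrose
    surv_yeast_slope: float
    sigma_log: float = 0.08
    t_min: float = 18.0  # physiological floor on development time

    def __post_init__(self):
        if self.sigma_log < 0:
            raise ValueError("dispersion must be non-negative")

    def median_dev_time(self, yeast_pct: float, sucrose_pct: float) -> float:
        t = self.t_base + self.t_sucrose_slope * sucrose_pct + self.t_yeast_slope * yeast_pct
        return max(t, self.t_min)

    def survival_prob(self, yeast_pct: float, sucrose_pct: float) -> float:
        return float(
            expit(
                self.surv_intercept
                + self.surv_sucrose_slope * sucrose_pct
                + self.surv_yeast_slope * yeast_pct
            )
        )


def tolerant_model(name: str = "tolerant") -> GenotypeDietModel:
    """A sugar-tolerant generalist: development and survival respond to
    yeast but are nearly flat along the sucrose axis."""
    return GenotypeDietModel(
        name=name,
        t_base=140.0,
        t_sucrose_slope=0.2,
        t_yeast_slope=-3.0,
        surv_intercept=0.5,
        surv_sucrose_slope=-0.01,
        surv_yeast_slope=0.15,
    )


def intolerant_model(name: str = "intolerant") -> GenotypeDietModel:
    """A sugar-intolerant specialist: dietary sucrose strongly delays
    development and depresses survival, to the point of near-lethality on a
    20% yeast / 20% sucrose diet."""
    return GenotypeDietModel(
        name=name,
        t_base=140.0,
        t_sucrose_slope=4.0,
        t_yeast_slope=-2.0,
        surv_intercept=0.5,
        surv_sucrose_slope=-0.25,
        surv_yeast_slope=0.10,
    )


def simulate_grid_assay(model: GenotypeDietModel, diets=DEFAULT_DIET_GRID,
                        n_reps: int = 5, n_larvae: int = 30,
                        obs_times=DEFAULT_OBS_TIMES, seed=None,
                        vial_effect_sd: float = 0.0) -> GridAssay:
    """Simulate cumulative pupariation counts over a diet grid.

    Per vial, each larva independently survives with the model's logistic
    probability; survivors pupariate at log-normally distributed times and
    cumulative counts are read off at the observation times.
    ``vial_effect_sd`` (log-scale sd, default off) adds a shared vial-level
    shift to development times.
    """
    diets = list(diets)
    if not diets:
        raise ValueError("empty diet list")
    times = np.asarray(obs_times, dtype=float)
    if times.size == 0 or (np.diff(times) <= 0).any() or times[0] <= 0:
        raise ValueError("observation times must be positive and strictly increasing")
    if n_larvae <= 0 or n_reps <= 0:
        raise ValueError("n_larvae and n_reps must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for yeast, suc in diets:
        p_surv = model.survival_prob(yeast, suc)
        mu = np.log(model.median_dev_time(yeast, suc))
        for vial in range(1, n_reps + 1):
            n_surv = rng.binomial(n_larvae, p_surv)
            shift = rng.normal(0.0, vial_effect_sd) if vial_effect_sd > 0 else 0.0
            if model.sigma_log > 0:
                dev = np.exp(rng.normal(mu + shift, model.sigma_log, size=n_surv))
            else:
                dev = np.full(n_surv, np.exp(mu + shift))
            dev.sort()
            cum = np.searchsorted(dev, times, side="right")
            for t, c in zip(times, cum):
                rows.append((model.name, yeast, suc, vial, t, int(c), n_larvae))
    return GridAssay(pd.DataFrame(rows, columns=GRID_ASSAY_COLUMNS))


# ---------------------------------------------------------------------------
# parental genomes


@dataclass(frozen=True)
class ParentalGenomeSpec:
    """Two diverged parental genomes over named chromosomes.

    ``fixed_diff_density`` is the per-bp rate of sites fixed for different
    alleles between the species; ``polymorphism_density`` (default one
    tenth of the fixed rate) is the per-bp rate of sites segregating within
    one species, which the diagnostic-SNP caller must exclude.
    ``n_sampled`` chromosomes per species are tallied in the genotype
    tables.
    """

    chromosomes: tuple = (("2", 20_000_000),)
    fixed_diff_density: float = 1e-3
    polymorphism_density: float = None
    n_sampled: int = 20

    def __post_init__(self):
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"zero-length chromosome {name!r}")
        if not 0 <= self.fixed_diff_density <= 1:
            raise ValueError("fixed-difference density must lie in [0, 1]")
        if self.polymorphism_density is None:
            object.__setattr__(
                self, "polymorphism_density", 0.1 * self.fixed_diff_density
            )
        if not 0 <= self.polymorphism_density <= 1:
            raise ValueError("polymorphism density must lie in [0, 1]")


def simulate_parental_genomes(spec: ParentalGenomeSpec, seed=None):
    """Genotype tables (chrom, pos 1-based, A/C/G/T counts) for two species.

    Fixed-difference sites carry all ``n_sampled`` observations on one
    allele in species A and on a different allele in species B.
    Polymorphic sites segregate two alleles within one randomly chosen
    species while the other species is fixed; fixed and polymorphic
    positions are disjoint.  Site counts per chromosome are Poisson in
    density x length.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_sampled
    rows_a, rows_b = [], []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for chrom, length in spec.chromosomes:
        n_fixed = rng.poisson(spec.fixed_diff_density * length)
        n_poly = rng.poisson(spec.polymorphism_density * length)
        pos = rng.choice(length, size=min(n_fixed + n_poly, length), replace=False) + 1
        fixed_pos = np.sort(pos[:n_fixed])
        poly_pos = np.sort(pos[n_fixed:])
        for p in fixed_pos:
            i, j = rng.choice(4, size=2, replace=False)
            ca = [0, 0, 0, 0]
            cb = [0, 0, 0, 0]
            ca[i] = n
            cb[j] = n
            rows_a.append((chrom, int(p), *ca))
            rows_b.append((chrom, int(p), *cb))
        for p in poly_pos:
            i, j = rng.choice(4, size=2, replace=False)
            minor = int(rng.integers(1, n))  # both alleles observed
            counts_poly = [0, 0, 0, 0]
            counts_poly[i] = n - minor
            counts_poly[j] = minor
            counts_fixed = [0, 0, 0, 0]
            counts_fixed[i] = n
            if rng.integers(2):  # polymorphic in species A
                rows_a.append((chrom, int(p), *counts_poly))
                rows_b.append((chrom, int(p), *counts_fixed))
            else:
                rows_a.append((chrom, int(p), *counts_fixed))
                rows_b.append((chrom, int(p), *counts_poly))
    cols = ["chrom", "pos", "A", "C", "G", "T"]
    table_a = pd.DataFrame(rows_a, columns=cols).sort_values(
        ["chrom", "pos"], ignore_index=True
    )
    table_b = pd.DataFrame(rows_b, columns=cols).sort_values(
        ["chrom", "pos"], ignore_index=True
    )
    return table_a, table_b


def write_genotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coding-sequence pairs


@dataclass(frozen=True)
class CodingPairSpec:
    """A pair of aligned coding sequences with exact substitution targets.

    ``n_nonsyn`` codons get a single amino-acid-changing difference and
    ``n_syn`` codons a single silent difference; every substituted codon
    differs at exactly one position, so downstream pathway classification
    recovers the targets exactly.
    """

    n_codons: int
    n_nonsyn: int = 0
    n_syn: int = 0

    def __post_init__(self):
        if self.n_nonsyn < 0 or self.n_syn < 0:
            raise ValueError("substitution targets must be non-negative")
        if self.n_nonsyn + self.n_syn > self.n_codons:
            raise ValueError(
                "infeasible targets: more substituted codons than codons"
            )


def _single_step_neighbors(codon: str):
    """(mutant codon, is_synonymous) for the 9 single-nucleotide mutants,
    excluding stops."""
    aa = CODON_TO_AA[codon]
    out = []
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            m = codon[:i] + b + codon[i + 1:]
            if m in STOP_CODONS:
                continue
            out.append((m, CODON_TO_AA[m] == aa))
    return out


def _place_substitutions(codons, n_nonsyn, n_syn, rng):
    """Give ``n_nonsyn`` codons one amino-acid-changing and ``n_syn`` codons
    one silent single-nucleotide change; at most one change per codon.

    Codons that cannot host the requested change class (e.g. ATG/TGG have
    no synonymous neighbour) are replaced by a freshly drawn codon;
    persistent failure raises.  ``codons`` is modified in place (sequence
    A); the return value is sequence B.
    """
    order = rng.permutation(len(codons))
    seq_b = list(codons)
    cursor = 0
    for kind, target in (("nonsyn", n_nonsyn), ("syn", n_syn)):
        done = 0
        attempts = 0
        while done < target:
            if cursor >= len(order):
                attempts += 1
                if attempts > 100:
                    raise ValueError(
                        f"infeasible targets: could not place {target - done} "
                        f"more {kind} substitutions in {len(codons)} codons"
                    )
                order = np.concatenate([order, rng.permutation(len(codons))])
            slot = order[cursor]
            cursor += 1
            if seq_b[slot] != codons[slot]:
                continue  # already substituted
            options = [
                m for m, is_syn in _single_step_neighbors(codons[slot])
                if is_syn == (kind == "syn")
            ]
            if not options:
                replacement = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
                codons[slot] = replacement
                seq_b[slot] = replacement
                options = [
                    m for m, is_syn in _single_step_neighbors(replacement)
                    if is_syn == (kind == "syn")
                ]
                if not options:
                    continue
            seq_b[slot] = options[rng.integers(len(options))]
            done += 1
    return seq_b


def simulate_coding_pair(spec: CodingPairSpec, seed=None):
    """Aligned coding-sequence pair ``(seq_a, seq_b)`` meeting the targets.

    Sequence A is a random sense-codon sequence; the requested numbers of
    codons are then given one nonsynonymous or one synonymous single-
    nucleotide change in sequence B.  No stop codons are introduced.
    Raises if a target cannot be met with the sampled codons.
    """
    rng = np.random.default_rng(seed)
    codons = [_SENSE_CODONS[i] for i in rng.integers(len(_SENSE_CODONS), size=spec.n_codons)]
    seq_b = _place_substitutions(codons, spec.n_nonsyn, spec.n_syn, rng)
    return "".join(codons), "".join(seq_b)


def simulate_neutral_coding_pair(n_codons: int, n_substitutions: int, seed=None):
    """A coding pair with equal per-site nonsynonymous and synonymous rates.

    The substitutions are split between amino-acid-changing and silent in
    proportion to the sequence's Nei–Gojobori nonsynonymous and synonymous
    site totals (N and S), so the two per-site rates are equal by
    construction and the Ka/Ks of the pair should sit near 1.  (A naive
    uniform point-mutation process with stop-codon rejection does *not*
    have equal per-site rates: rejecting the would-be-stop mutations, which
    are all nonsynonymous, depresses the nonsynonymous rate by several
    percent.)  Each substituted codon carries a single-nucleotide change;
    no stop codons are introduced.
    """
    from .seqdiv import classify_substitutions

    if n_substitutions > n_codons:
        raise ValueError("at most one substitution per codon is supported")
    rng = np.random.default_rng(seed)
    codons = [_SENSE_CODONS[i] for i in rng.integers(len(_SENSE_CODONS), size=n_codons)]
    seq_a = "".join(codons)
    sites = classify_substitutions(seq_a, seq_a)
    p_nonsyn = sites.nonsyn_sites / (sites.nonsyn_sites + sites.syn_sites)
    k_nonsyn = int(round(n_substitutions * p_nonsyn))
    seq_b = _place_substitutions(codons, k_nonsyn, n_substitutions - k_nonsyn, rng)
    return "".join(codons), "".join(seq_b)


def write_fasta_pair(pair, path, ids=("species_A", "species_B")) -> None:
    """Two aligned records as FASTA (equal length, length divisible by 3
    for coding pairs)."""
    seq_a, seq_b = pair
    with open(path, "w") as fh:
        for name, seq in zip(ids, (seq_a, seq_b)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
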