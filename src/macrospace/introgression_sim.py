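"""Forward simulator of phenotype-based backcross introgression.

Models the crossing scheme used to move a dietary-tolerance phenotype from a
donor species (*D. simulans*) into a recipient background (*D. sechellia*):
donor females are crossed to recipient males, then hybrid females are
backcrossed to recipient males for ``g`` generations with optional survival
selection requiring donor alleles at configured tolerance loci, followed by
several generations of sib-mating.  Genomes are tracked as ancestry tracts —
contiguous segments of donor or recipient origin delimited by recombination
breakpoints.

Biology encoded here:

* recombination happens only in females (Drosophila males are achiasmatic);
* crossover counts are Poisson in the chromosome's genetic length (no
  interference), breakpoints uniform on physical length;
* mitochondria are strictly maternal, so every descendant of the original
  donor females carries donor mitochondria;
* males are hemizygous for the X, which they inherit from their mother.

Coordinates are 0-based half-open throughout; BED output keeps that
convention, TSV positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DONOR",
    "RECIPIENT",
    "Chromosome",
    "ChromosomeMap",
    "Individual",
    "IntrogressionScheme",
    "ExtinctionError",
    "default_chromosome_map",
    "make_f1",
    "meiosis",
    "backcross_generation",
    "sib_generation",
    "run_introgression",
    "pool_counts",
    "donor_fraction",
    "expected_donor_fraction",
    "donor_tract_containing",
    "write_ancestry_bed",
]

RECIPIENT = 0
DONOR = 1

# A haplotype is a list of (start, end, origin) tracts tiling [0, length),
# half-open, sorted, with adjacent tracts of distinct origin.
Tracts = list


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    genetic_length_m: float  # Morgans; 0 for the mitochondrion
    kind: str = "autosome"  # autosome | X | mito

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("chromosome length must be positive")
        if self.genetic_length_m < 0:
            raise ValueError("genetic length must be non-negative")
        if self.kind == "mito" and self.genetic_length_m != 0:
            raise ValueError("mitochondrial genetic length must be 0")
        if self.kind not in ("autosome", "X", "mito"):
            raise ValueError(f"unknown inheritance class {self.kind!r}")


@dataclass(frozen=True)
class ChromosomeMap:
    chromosomes: tuple

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        if sum(c.kind == "mito" for c in self.chromosomes) != 1:
            raise ValueError("a chromosome map needs exactly one mitochondrial element")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    def __iter__(self):
        return iter(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def autosomes(self):
        return [c for c in self.chromosomes if c.kind == "autosome"]

    @property
    def x(self) -> Chromosome:
        xs = [c for c in self.chromosomes if c.kind == "X"]
        if not xs:
            raise KeyError("no X chromosome in map")
        return xs[0]


def default_chromosome_map() -> ChromosomeMap:
    """Two major autosomes, an X and the mitochondrion.

    Genetic lengths default to 1.1 M (chr2), 1.1 M (chr3) and 0.7 M (X);
    the dot chromosome and heterochromatin are ignored.
    """
    return ChromosomeMap(
        (
            Chromosome("2", 47_000_000, 1.1),
            Chromosome("3", 53_000_000, 1.1),
            Chromosome("X", 23_000_000, 0.7, kind="X"),
            Chromosome("mito", 19_000, 0.0, kind="mito"),
        )
    )


@dataclass
class Individual:
    """One fly: per-chromosome ancestry haplotypes plus sex and mito origin.

    ``haplotypes[name]`` holds two tract lists for autosomes, two for a
    female X and one for a male X; the mitochondrion is the scalar
    ``mito_origin``.
    """

    sex: str  # 'F' or 'M'
    haplotypes: dict
    mito_origin: int

    def validate(self, cmap: ChromosomeMap) -> None:
        for chrom in cmap:
            if chrom.kind == "mito":
                continue
            haps = self.haplotypes[chrom.name]
            expected = 1 if (chrom.kind == "X" and self.sex == "M") else 2
            if len(haps) != expected:
                raise ValueError(
                    f"{self.sex} individual has {len(haps)} haplotypes on {chrom.name}"
                )
            for hap in haps:
                _check_tracts(hap, chrom.length_bp)


class ExtinctionError(RuntimeError):
    """Raised when selection leaves no viable offspring to fill a generation."""

    def __init__(self, generation: int):
        super().__init__(f"population went extinct under selection at generation {generation}")
        self.generation = generation


@dataclass(frozen=True)
class IntrogressionScheme:
    """Parameters of the backcross-with-selection scheme.

    ``n_backcross`` generations of crossing hybrid females to recipient
    males (default 10), followed by ``n_sib_mating`` generations of
    within-line mating (default 3).  When ``selection`` is on, offspring of
    the selective cross survive only per the selection model at the
    ``tolerance_loci``: with ``selection_model='all_required'`` survival
    requires at least one donor allele at every locus (dominant rescue);
    with ``'independent'`` each locus contributes an independent survival
    probability (``p_with_donor`` if a donor allele is present, else
    ``p_without_donor``).
    """

    n_backcross: int = 10
    selection: bool = True
    tolerance_loci: tuple = (("2", 6_000_000),)
    selection_model: str = "all_required"
    p_with_donor: float = 1.0
    p_without_donor: float = 0.0
    population_size: int = 200
    n_sib_mating: int = 3
    max_attempts_factor: int = 500

    def __post_init__(self):
        if self.n_backcross < 0:
            raise ValueError("number of backcross generations must be >= 0")
        if self.population_size <= 0:
            raise ValueError("population size must be positive")
        if self.selection_model not in ("all_required", "independent"):
            raise ValueError(f"unknown selection model {self.selection_model!r}")

    def validate_loci(self, cmap: ChromosomeMap) -> None:
        for chrom, pos in self.tolerance_loci:
            c = cmap[chrom]
            if not 0 <= pos < c.length_bp:
                raise ValueError(f"locus {chrom}:{pos} outside chromosome bounds")


# ---------------------------------------------------------------------------
# tract bookkeeping


def _check_tracts(tracts: Tracts, length: int) -> None:
    if not tracts:
        raise ValueError("empty tract list")
    if tracts[0][0] != 0 or tracts[-1][1] != length:
        raise ValueError("tracts must tile [0, length)")
    prev_end = 0
    prev_origin = None
    for start, end, origin in tracts:
        if start != prev_end or end <= start:
            raise ValueError("tracts must be sorted, non-overlapping and contiguous")
        if origin == prev_origin:
            raise ValueError("adjacent tracts must differ in origin")
        prev_end, prev_origin = end, origin


def _normalize(tracts: Tracts) -> Tracts:
    """Merge adjacent tracts with equal origin."""
    out = []
    for start, end, origin in tracts:
        if out and out[-1][2] == origin:
            out[-1] = (out[-1][0], end, origin)
        else:
            out.append((start, end, origin))
    return out


def _slice_tracts(tracts: Tracts, lo: int, hi: int) -> Tracts:
    """Tracts of ``tracts`` clipped to [lo, hi)."""
    out = []
    for start, end, origin in tracts:
        if end <= lo:
            continue
        if start >= hi:
            break
        out.append((max(start, lo), min(end, hi), origin))
    return out


def _origin_at(tracts: Tracts, pos: int) -> int:
    for start, end, origin in tracts:
        if start <= pos < end:
            return origin
    raise IndexError(f"position {pos} outside haplotype")


def _recombine(hap_a: Tracts, hap_b: Tracts, breakpoints, start_with_a: bool) -> Tracts:
    """Splice two haplotypes at the given sorted breakpoints."""
    length = hap_a[-1][1]
    bounds = [0, *breakpoints, length]
    out = []
    use_a = start_with_a
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi > lo:
            out.extend(_slice_tracts(hap_a if use_a else hap_b, lo, hi))
        use_a = not use_a
    return _normalize(out)


def donor_fraction(ind: Individual, cmap: ChromosomeMap, kinds=("autosome",)) -> float:
    """Fraction of the individual's genome (of the given classes) of donor origin."""
    donor_bp = 0
    total_bp = 0
    for chrom in cmap:
        if chrom.kind not in kinds:
            continue
        for hap in ind.haplotypes[chrom.name]:
            donor_bp += sum(end - start for start, end, o in hap if o == DONOR)
            total_bp += chrom.length_bp
    if total_bp == 0:
        raise ValueError("no chromosomes of the requested classes")
    return donor_bp / total_bp


def donor_tract_containing(ind: Individual, chrom: str, pos: int):
    """The (start, end) of a donor tract covering ``pos`` on either haplotype,
    or None if neither haplotype is donor there."""
    best = None
    for hap in ind.haplotypes[chrom]:
        for start, end, origin in hap:
            if origin == DONOR and start <= pos < end:
                if best is None or (end - start) > (best[1] - best[0]):
                    best = (start, end)
    return best


# ---------------------------------------------------------------------------
# crossing operations


def _pure_hap(length: int, origin: int) -> Tracts:
    return [(0, length, origin)]


def make_f1(n: int, cmap: ChromosomeMap, seed=None) -> list:
    """F1 hybrid females from donor mothers x recipient fathers.

    Every F1 is heterozygous donor/recipient along every autosome and the X,
    and carries donor (maternal) mitochondria.  Only females are returned —
    F1 males are not used in the backcross scheme (and interspecific hybrid
    males are sterile in any case).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    pop = []
    for _ in range(n):
        haps = {}
        for chrom in cmap:
            if chrom.kind == "mito":
                continue
            haps[chrom.name] = [
                _pure_hap(chrom.length_bp, DONOR),
                _pure_hap(chrom.length_bp, RECIPIENT),
            ]
        pop.append(Individual(sex="F", haplotypes=haps, mito_origin=DONOR))
    return pop


def meiosis(mother: Individual, chrom: Chromosome, rng: np.random.Generator) -> Tracts:
    """One female gamete haplotype for ``chrom``.

    Crossover count is Poisson in the genetic length; breakpoints are
    uniform on physical length.  Male meiosis (no recombination) is a plain
    haplotype choice and must not go through here.
    """
    if mother.sex != "F":
        raise ValueError("recombination is female-only; male gametes are whole haplotypes")
    hap_a, hap_b = mother.haplotypes[chrom.name]
    n_cx = rng.poisson(chrom.genetic_length_m)
    start_with_a = bool(rng.integers(2))
    if n_cx == 0:
        return list(hap_a if start_with_a else hap_b)
    breakpoints = np.sort(rng.integers(1, chrom.length_bp, size=n_cx)).tolist()
    return _recombine(hap_a, hap_b, breakpoints, start_with_a)


def _male_gamete(father: Individual, chrom: Chromosome, rng: np.random.Generator):
    """Male gamete: an unrecombined haplotype; for the X, half the gametes
    carry the X and half the (untracked) Y — returns None for Y gametes."""
    if chrom.kind == "X":
        if rng.integers(2):
            return None  # Y-bearing sperm -> son
        return list(father.haplotypes[chrom.name][0])
    haps = father.haplotypes[chrom.name]
    return list(haps[rng.integers(len(haps))])


def _survives_selection(ind: Individual, scheme: IntrogressionScheme,
                        rng: np.random.Generator) -> bool:
    if not scheme.selection:
        return True
    p = 1.0
    for chrom, pos in scheme.tolerance_loci:
        has_donor = any(
            _origin_at(hap, pos) == DONOR for hap in ind.haplotypes[chrom]
        )
        if scheme.selection_model == "all_required":
            if not has_donor:
                return False
        else:
            p *= scheme.p_with_donor if has_donor else scheme.p_without_donor
    if scheme.selection_model == "independent":
        return bool(rng.random() < p)
    return True


def _offspring(mother: Individual, father_haps, cmap: ChromosomeMap,
               rng: np.random.Generator, father: Individual = None) -> Individual:
    """One offspring from a mother and either a pure-recipient father
    (father_haps=None, father=None) or an explicit father individual."""
    haps = {}
    # decide sex via the paternal X/Y gamete
    x = cmap.x
    if father is None:
        paternal_x = None if rng.integers(2) else _pure_hap(x.length_bp, RECIPIENT)
    else:
        paternal_x = _male_gamete(father, x, rng)
    sex = "M" if paternal_x is None else "F"
    for chrom in cmap:
        if chrom.kind == "mito":
            continue
        maternal = meiosis(mother, chrom, rng)
        if chrom.kind == "X":
            haps[chrom.name] = [maternal] if sex == "M" else [maternal, paternal_x]
        else:
            if father is None:
                paternal = _pure_hap(chrom.length_bp, RECIPIENT)
            else:
                paternal = _male_gamete(father, chrom, rng)
            haps[chrom.name] = [maternal, paternal]
    return Individual(sex=sex, haplotypes=haps, mito_origin=mother.mito_origin)


def _fill_generation(produce, scheme: IntrogressionScheme,
                     rng: np.random.Generator, generation: int,
                     need_female: bool, need_male: bool) -> list:
    """Collect ``population_size`` surviving offspring from ``produce``.

    Guarantees at least one offspring of each sex the next cross requires
    (the breeding protocol collects virgin females every generation, so a
    line is only lost when selection, not sex ratio, prevents it): once the
    census is full, offspring of a still-missing sex replace a random
    individual of the other sex.  The attempt budget converts persistent
    failure into :class:`ExtinctionError`.
    """
    survivors: list = []
    n_female = 0
    max_attempts = scheme.max_attempts_factor * scheme.population_size
    attempts = 0
    size = scheme.population_size

    def satisfied():
        n_male = len(survivors) - n_female
        return (
            len(survivors) >= size
            and (not need_female or n_female > 0)
            and (not need_male or n_male > 0)
        )

    while not satisfied():
        if attempts >= max_attempts:
            raise ExtinctionError(generation)
        attempts += 1
        child = produce()
        if not _survives_selection(child, scheme, rng):
            continue
        if len(survivors) < size:
            survivors.append(child)
            n_female += child.sex == "F"
        elif child.sex == "F" and need_female and n_female == 0:
            males = [i for i, s in enumerate(survivors) if s.sex == "M"]
            survivors[males[rng.integers(len(males))]] = child
            n_female += 1
        elif child.sex == "M" and need_male and n_female == len(survivors):
            females = [i for i, s in enumerate(survivors) if s.sex == "F"]
            survivors[females[rng.integers(len(females))]] = child
            n_female -= 1
    return survivors


def backcross_generation(females: list, scheme: IntrogressionScheme,
                         cmap: ChromosomeMap, rng: np.random.Generator,
                         generation: int = 0, need_male: bool = False) -> list:
    """One backcross: hybrid females x pure recipient males, with selection.

    Offspring receive one recombinant maternal gamete and one pure-recipient
    paternal gamete (daughters also a recipient X; sons the maternal X only).
    Under selection, offspring are produced until ``population_size``
    survivors accumulate; exceeding the attempt budget raises
    :class:`ExtinctionError` with the generation index.
    """
    mothers = [f for f in females if f.sex == "F"]
    if not mothers:
        raise ValueError("no females available for backcrossing")

    def produce():
        mother = mothers[rng.integers(len(mothers))]
        return _offspring(mother, None, cmap, rng)

    return _fill_generation(produce, scheme, rng, generation,
                            need_female=True, need_male=need_male)


def sib_generation(population: list, scheme: IntrogressionScheme,
                   cmap: ChromosomeMap, rng: np.random.Generator,
                   generation: int = 0) -> list:
    """One generation of within-line (sib) mating with the same selection."""
    mothers = [i for i in population if i.sex == "F"]
    fathers = [i for i in population if i.sex == "M"]
    if not mothers or not fathers:
        raise ExtinctionError(generation)

    def produce():
        mother = mothers[rng.integers(len(mothers))]
        father = fathers[rng.integers(len(fathers))]
        return _offspring(mother, None, cmap, rng, father=father)

    return _fill_generation(produce, scheme, rng, generation,
                            need_female=True, need_male=True)


@dataclass
class IntrogressionResult:
    population: list
    trace: pd.DataFrame  # per generation: label, mean autosomal/X donor fraction


def run_introgression(scheme: IntrogressionScheme, cmap: ChromosomeMap = None,
                      seed=None) -> IntrogressionResult:
    """Run the full scheme: F1, ``n_backcross`` selective backcrosses, then
    sib-mating; returns the final population and a per-generation trace of
    mean donor fractions."""
    if cmap is None:
        cmap = default_chromosome_map()
    scheme.validate_loci(cmap)
    rng = np.random.default_rng(seed)
    pop = make_f1(scheme.population_size, cmap, seed=None)
    records = []

    def record(label, population):
        records.append(
            {
                "generation": label,
                "n": len(population),
                "donor_fraction_autosome": float(
                    np.mean([donor_fraction(i, cmap, ("autosome",)) for i in population])
                ),
                "donor_fraction_x": float(
                    np.mean([donor_fraction(i, cmap, ("X",)) for i in population])
                ),
                "mito_donor_fraction": float(
                    np.mean([i.mito_origin == DONOR for i in population])
                ),
            }
        )

    record("F1", pop)
    for g in range(1, scheme.n_backcross + 1):
        last = g == scheme.n_backcross
        pop = backcross_generation(
            pop, scheme, cmap, rng, generation=g,
            need_male=last and scheme.n_sib_mating > 0,
        )
        record(f"BC{g}", pop)
    for s in range(1, scheme.n_sib_mating + 1):
        pop = sib_generation(pop, scheme, cmap, rng,
                             generation=scheme.n_backcross + s)
        record(f"SIB{s}", pop)
    return IntrogressionResult(population=pop, trace=pd.DataFrame(records))


def expected_donor_fraction(n_backcross: int) -> dict:
    """Analytic expected donor fraction after ``n_backcross`` selection-free
    backcrosses, by inheritance class.

    Small dynamic program: an F1 female is half donor everywhere; each
    backcross pairs an unbiased maternal gamete (expectation = the mother's
    mean) with a pure recipient paternal genome, halving the expectation on
    autosomes and on the female X alike.  Mitochondria stay donor.
    """
    auto = 0.5
    x_f = 0.5
    for _ in range(n_backcross):
        auto = auto / 2.0
        x_f = x_f / 2.0  # daughter X = (maternal gamete ~ x_f) paired with recipient X
    return {"autosome": auto, "X_female": x_f, "mito": 1.0}


# ---------------------------------------------------------------------------
# pooled-sequencing readout


def pool_counts(population: list, snps: pd.DataFrame, mean_depth: float,
                n_pooled_females: int, seed=None) -> pd.DataFrame:
    """Pooled resequencing of sampled females at species-diagnostic SNPs.

    Per SNP, sequencing depth is Poisson(``mean_depth``) and the donor-allele
    read count is Binomial(depth, donor allele frequency among the pooled
    haplotypes).  ``snps`` needs columns chrom, pos (1-based).  Returns a
    table chrom, pos, depth, donor_reads.
    """
    females = [i for i in population if i.sex == "F"]
    if not females:
        raise ValueError("empty population (no females to pool)")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(females), size=min(n_pooled_females, len(females)), replace=False)
    sampled = [females[i] for i in idx]

    out = []
    for chrom, group in snps.groupby("chrom", sort=False):
        pos0 = group["pos"].to_numpy(np.int64) - 1  # internal 0-based
        donor_alleles = np.zeros(len(pos0), dtype=np.int64)
        n_haps = 0
        for ind in sampled:
            for hap in ind.haplotypes[chrom]:
                ends = np.fromiter((t[1] for t in hap), dtype=np.int64, count=len(hap))
                origins = np.fromiter((t[2] for t in hap), dtype=np.int64, count=len(hap))
                donor_alleles += origins[np.searchsorted(ends, pos0, side="right")] == DONOR
                n_haps += 1
        freq = donor_alleles / n_haps
        depth = rng.poisson(mean_depth, size=len(pos0))
        reads = rng.binomial(depth, freq)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": group["pos"].to_numpy(),
                    "depth": depth,
                    "donor_reads": reads,
                }
            )
        )
    if not out:
        raise ValueError("no SNPs supplied")
    return pd.concat(out, ignore_index=True)


def write_ancestry_bed(ind: Individual, cmap: ChromosomeMap, path) -> None:
    """Write the individual's donor tracts as BED (0-based half-open),
    one record per donor tract, name = haplotype index."""
    rows = []
    for chrom in cmap:
        if chrom.kind == "mito":
            continue
        for h, hap in enumerate(ind.haplotypes[chrom.name]):
            for start, end, origin in hap:
                if origin == DONOR:
                    rows.append(f"{chrom.name}\t{start}\t{end}\thap{h}")
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))
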