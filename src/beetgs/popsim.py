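"""Forward simulator for breeding populations of partially inbred lines.

Emulates the data structure of a typical (sugar beet) line-breeding
program: a large diversity set of unrelated-ish inbred lines drawn from a
finite founder pool, plus biparental families connected through one common
parent, genotyped with a genome-wide SNP map and testcross-phenotyped at a
handful of locations.

The simulator works on haplotypes.  Quantitative-trait loci are hidden
loci interleaved with the observed marker map: haplotypes carry markers
and QTL jointly through meiosis, but the marker matrix handed to the
analysis only ever contains marker columns.  Genetic values are purely
additive sums over QTL dosages, optionally topped up with an infinitesimal
polygenic term so the realized entry-mean heritability matches a target.

Recombination follows the Haldane model: crossover counts per chromosome
are Poisson(length in Morgans) with positions uniform, no interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GeneticMap, MarkerMatrix, PhenotypeRecords

__all__ = [
    "PopulationDesign",
    "FamilySpec",
    "QTLModel",
    "TrialDesign",
    "Population",
    "TRAIT_TARGET_H2",
    "simulate_map",
    "simulate_founders",
    "meiosis",
    "draw_qtl",
    "make_population",
    "simulate_phenotypes",
    "flip_linkage_phase",
    "simulate_study",
]

# Per-trait target entry-mean heritabilities for the default six-trait study:
# white sugar yield, sugar content, root yield, sodium, potassium,
# alpha-amino nitrogen, spanning the 0.38-0.71 range typical of multi-location
# sugar beet testcross trials (alpha-amino N is the hardest trait).
TRAIT_TARGET_H2 = {
    "WSY": 0.71,
    "SC": 0.65,
    "RY": 0.60,
    "Na": 0.55,
    "K": 0.48,
    "N": 0.38,
}


# ---------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class FamilySpec:
    """One biparental family: parent line ids and number of progeny lines.

    ``parent_a=None`` means "use the population's common parent";
    ``parent_b=None`` means "sample a parent from the diversity set".
    """

    family_id: str
    n_progeny: int
    parent_a: str | None = None
    parent_b: str | None = None


def _default_families() -> tuple[FamilySpec, ...]:
    return tuple(FamilySpec(f"Family{i}", 62) for i in range(1, 5))


@dataclass(frozen=True)
class PopulationDesign:
    """Composition of the simulated population.

    Defaults reproduce the study layout: 676 diversity lines plus four
    62-progeny biparental families (248 lines, 924 total) sharing one
    common parent, with equal proportions of S1/S2/S3 inbreds.
    """

    n_diversity: int = 676
    families: tuple[FamilySpec, ...] = field(default_factory=_default_families)
    selfing_generations: tuple[int, ...] = (1, 2, 3)
    common_parent: str | None = None

    @property
    def n_family_lines(self) -> int:
        return sum(f.n_progeny for f in self.families)

    @property
    def n_lines(self) -> int:
        return self.n_diversity + self.n_family_lines


@dataclass(frozen=True)
class QTLModel:
    """Additive QTL: genome positions and per-QTL effects in trait units."""

    chromosomes: np.ndarray
    positions: np.ndarray
    effects: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", np.asarray(self.chromosomes, dtype=np.int64))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "effects", np.asarray(self.effects, dtype=float))
        if not (len(self.chromosomes) == len(self.positions) == len(self.effects)):
            raise ValueError("QTL arrays must have equal length")

    @property
    def n_qtl(self) -> int:
        return len(self.effects)


@dataclass(frozen=True)
class TrialDesign:
    """Multi-location testcross trial layout and trait variance targets.

    ``locations_per_line`` is the set a line's location count is drawn from
    (uniformly); use a single-element tuple for balanced trials.
    ``target_h2`` is the entry-mean heritability the simulated trait should
    realize; ``polygenic_fraction`` is the share of genetic variance carried
    by the infinitesimal (non-QTL) term.
    """

    n_locations_total: int = 7
    locations_per_line: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    location_effect_sd: float = 1.0
    gxe_plus_error_sd: float = 1.0
    target_h2: float | None = 0.6
    mu: float = 0.0
    polygenic_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.target_h2 is not None and not (0.0 < self.target_h2 <= 1.0):
            raise ValueError("target_h2 must lie in (0, 1]")
        if any(c < 1 or c > self.n_locations_total for c in self.locations_per_line):
            raise ValueError("locations_per_line entries must lie in 1..n_locations_total")
        if not (0.0 <= self.polygenic_fraction <= 1.0):
            raise ValueError("polygenic_fraction must lie in [0, 1]")


@dataclass
class Population:
    """Simulated lines with full haplotypes over markers + hidden QTL loci.

    ``loci`` covers every simulated locus; ``qtl_mask`` marks the hidden QTL
    columns.  ``haplotypes`` has shape (n_lines, 2, n_loci) with 0/1 alleles.
    """

    loci: GeneticMap
    qtl_mask: np.ndarray
    haplotypes: np.ndarray
    line_ids: np.ndarray
    membership: pd.Series  # line_id -> "diversity" | family_id
    selfing_gen: np.ndarray  # per-line number of selfing generations

    @property
    def n_lines(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def marker_map(self) -> GeneticMap:
        return self.loci.subset(~self.qtl_mask)

    def marker_matrix(self) -> MarkerMatrix:
        X = self.haplotypes[:, :, ~self.qtl_mask].sum(axis=1).astype(float)
        return MarkerMatrix(X, self.line_ids, self.loci.marker_ids[~self.qtl_mask])

    def qtl_dosages(self) -> np.ndarray:
        return self.haplotypes[:, :, self.qtl_mask].sum(axis=1).astype(float)

    def lines_in(self, group: str) -> np.ndarray:
        """Row indices of the lines belonging to a membership group."""
        ids = self.membership.index[self.membership == group]
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        return np.array([lookup[lid] for lid in ids], dtype=np.intp)

    def heterozygosity(self) -> np.ndarray:
        """Per-line fraction of heterozygous loci (over all simulated loci)."""
        return (self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean(axis=1)


# ---------------------------------------------------------------------------
# map and founders


def simulate_map(
    n_chromosomes: int,
    n_markers: int,
    total_length_cM: float,
    max_gap_cM: float,
    seed: int | np.random.Generator,
) -> GeneticMap:
    """Random marker map with a fixed total length and a hard gap cap.

    Markers are spread over ``n_chromosomes`` chromosomes of equal genetic
    length; within a chromosome the first/last markers sit at the ends (so
    the realized length is exact) and interior gaps are exponential-ish
    random, rescaled to the chromosome length and redistributed until no
    gap exceeds ``max_gap_cM``.
    """
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    if n_markers < 2 * n_chromosomes:
        raise ValueError("need >= 2 markers per chromosome to realize chromosome spans")
    if total_length_cM <= 0:
        raise ValueError("total_length_cM must be positive")
    rng = np.random.default_rng(seed)

    base, extra = divmod(n_markers, n_chromosomes)
    counts = np.full(n_chromosomes, base)
    counts[:extra] += 1
    chrom_len = total_length_cM / n_chromosomes
    if np.any((counts - 1) * max_gap_cM < chrom_len - 1e-9):
        raise ValueError(
            "infeasible map: max_gap_cM too small for the requested marker density"
        )

    ids, chroms, positions = [], [], []
    for c in range(1, n_chromosomes + 1):
        k = counts[c - 1]
        gaps = rng.exponential(1.0, size=k - 1)
        gaps *= chrom_len / gaps.sum()
        # cap-and-redistribute until every gap respects the maximum
        for _ in range(1000):
            over = gaps > max_gap_cM
            if not over.any():
                break
            excess = (gaps[over] - max_gap_cM).sum()
            gaps[over] = max_gap_cM
            room = ~over
            gaps[room] += excess * gaps[room] / gaps[room].sum()
        else:  # pragma: no cover - guarded by the feasibility check above
            raise RuntimeError("gap redistribution failed to converge")
        pos = np.concatenate([[0.0], np.cumsum(gaps)])
        pos[-1] = chrom_len  # exact endpoint despite float accumulation
        chroms.extend([c] * k)
        positions.extend(pos.tolist())
    ids = [f"M{c}_{i:04d}" for c, i in zip(chroms, range(len(chroms)))]
    return GeneticMap(np.array(ids, dtype=object), chroms, positions)


def simulate_founders(
    n_founders: int,
    gmap: GeneticMap,
    maf_range: tuple[float, float],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes in linkage equilibrium, shape (n_founders, 2, n_loci).

    Per marker, a target minor-allele frequency is drawn uniformly from
    ``maf_range`` and realized exactly as an allele count over the 2*n
    founder haplotypes (randomly permuted per marker, so founder loci are
    independent).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_founders
    m = gmap.n_markers
    target = rng.uniform(lo, hi, size=m)
    counts = np.clip(
        np.round(target * n_hap).astype(int),
        max(1, math.ceil(lo * n_hap - 1e-9)),
        n_hap // 2,
    )
    haps = np.zeros((n_hap, m), dtype=np.int8)
    for j in range(m):
        carriers = rng.choice(n_hap, size=counts[j], replace=False)
        haps[carriers, j] = 1
    return haps.reshape(n_founders, 2, m)


# ---------------------------------------------------------------------------
# recombination


def _chrom_blocks(gmap: GeneticMap) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (index array, position array)."""
    blocks = []
    for c in gmap.chromosome_ids:
        idx = np.flatnonzero(gmap.chromosomes == c)
        blocks.append((idx, gmap.positions[idx]))
    return blocks


def meiosis(
    parent_haplotypes: np.ndarray,
    gmap: GeneticMap,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One gamete from a diploid parent under the Haldane model.

    ``parent_haplotypes`` has shape (2, n_loci) aligned to ``gmap``.
    Crossover counts per chromosome are Poisson(length in Morgans) with
    uniform positions; the gamete is the resulting mosaic of the two
    parental haplotypes.
    """
    parent_haplotypes = np.asarray(parent_haplotypes)
    if parent_haplotypes.shape != (2, gmap.n_markers):
        raise ValueError("parent haplotypes must have shape (2, n_loci) matching the map")
    rng = np.random.default_rng(seed)
    return _gamete(parent_haplotypes, _chrom_blocks(gmap), rng)


def _gamete(hap: np.ndarray, blocks: list[tuple[np.ndarray, np.ndarray]],
            rng: np.random.Generator) -> np.ndarray:
    gam = np.empty(hap.shape[1], dtype=hap.dtype)
    for idx, pos in blocks:
        span = pos[-1] - pos[0]
        n_co = rng.poisson(span / 100.0) if span > 0 else 0
        start = rng.integers(2)
        if n_co == 0:
            gam[idx] = hap[start, idx]
            continue
        xo = rng.uniform(pos[0], pos[-1], size=n_co)
        parity = (start + np.searchsorted(np.sort(xo), pos, side="right")) % 2
        gam[idx] = hap[parity, idx]
    return gam


def _self_chain(hap: np.ndarray, g: int, blocks, rng) -> np.ndarray:
    """Self a diploid individual for g generations (single-seed descent)."""
    ind = hap
    for _ in range(g):
        ind = np.stack([_gamete(ind, blocks, rng), _gamete(ind, blocks, rng)])
    return ind


# ---------------------------------------------------------------------------
# QTL and combined locus sets


def draw_qtl(
    gmap: GeneticMap,
    n_qtl: int,
    seed: int | np.random.Generator,
    effect_sd: float = 1.0,
) -> QTLModel:
    """Place QTL uniformly on the map's chromosome spans with N(0, sd²) effects."""
    rng = np.random.default_rng(seed)
    spans = {int(c): gmap.chromosome_span(c) for c in gmap.chromosome_ids}
    lengths = np.array([hi - lo for lo, hi in spans.values()])
    probs = lengths / lengths.sum()
    chroms = rng.choice(list(spans), size=n_qtl, p=probs)
    pos = np.array([rng.uniform(*spans[int(c)]) for c in chroms])
    effects = rng.normal(0.0, effect_sd, size=n_qtl)
    return QTLModel(chroms, pos, effects)


def _merge_loci(gmap: GeneticMap, qtl: QTLModel | None) -> tuple[GeneticMap, np.ndarray, np.ndarray]:
    """Interleave QTL loci into the marker map.

    Returns (combined map, qtl_mask, qtl_column_order) where
    ``qtl_column_order[k]`` is the combined-map column of the k-th QTL.
    """
    if qtl is None or qtl.n_qtl == 0:
        return gmap, np.zeros(gmap.n_markers, dtype=bool), np.empty(0, dtype=np.intp)
    ids = np.concatenate([gmap.marker_ids,
                          np.array([f"QTL_{k}" for k in range(qtl.n_qtl)], dtype=object)])
    chroms = np.concatenate([gmap.chromosomes, qtl.chromosomes])
    pos = np.concatenate([gmap.positions, qtl.positions])
    is_qtl = np.concatenate([np.zeros(gmap.n_markers, bool), np.ones(qtl.n_qtl, bool)])
    qtl_no = np.concatenate([np.full(gmap.n_markers, -1), np.arange(qtl.n_qtl)])
    # nudge exact position collisions so within-chromosome order stays strict
    order = np.lexsort((is_qtl, pos, chroms))
    for c in np.unique(chroms):
        sel = order[chroms[order] == c]
        p = pos[sel]
        for i in range(1, len(p)):
            if p[i] <= p[i - 1]:
                p[i] = p[i - 1] + 1e-6
        pos[sel] = p
    combined = GeneticMap(ids[order], chroms[order], pos[order])
    qtl_mask = is_qtl[order]
    inv = np.empty(qtl.n_qtl, dtype=np.intp)
    ranks = qtl_no[order]
    for col, k in enumerate(ranks):
        if k >= 0:
            inv[k] = col
    return combined, qtl_mask, inv


# ---------------------------------------------------------------------------
# population construction


def make_population(
    design: PopulationDesign,
    founders: np.ndarray,
    loci: GeneticMap,
    seed: int | np.random.Generator,
    qtl_mask: np.ndarray | None = None,
) -> Population:
    """Build the diversity set + biparental families from a founder pool.

    Diversity lines: cross two random distinct founders, then self for a
    generation count drawn from ``design.selfing_generations`` (single-seed
    descent).  Family lines: one F1 per family from the two parent lines
    (the common parent plus a second parent), each progeny an independent
    selfing chain from that F1.
    """
    rng = np.random.default_rng(seed)
    founders = np.asarray(founders)
    if founders.ndim != 3 or founders.shape[1] != 2 or founders.shape[2] != loci.n_markers:
        raise ValueError("founders must have shape (n_founders, 2, n_loci) matching loci")
    if qtl_mask is None:
        qtl_mask = np.zeros(loci.n_markers, dtype=bool)
    blocks = _chrom_blocks(loci)
    n_f = founders.shape[0]
    gens = np.asarray(design.selfing_generations)

    hap_list, ids, groups, sgens = [], [], [], []
    div_haps: dict[str, np.ndarray] = {}
    for i in range(design.n_diversity):
        a, b = rng.choice(n_f, size=2, replace=False)
        f1 = np.stack([_gamete(founders[a], blocks, rng), _gamete(founders[b], blocks, rng)])
        g = int(rng.choice(gens))
        ind = _self_chain(f1, g, blocks, rng)
        lid = f"DIV_{i + 1:04d}"
        div_haps[lid] = ind
        hap_list.append(ind)
        ids.append(lid)
        groups.append("diversity")
        sgens.append(g)

    def _resolve(parent: str | None, taken: set[str]) -> str:
        if parent is not None:
            if parent not in div_haps:
                raise KeyError(f"unknown parent line id: {parent}")
            return parent
        pool = [lid for lid in div_haps if lid not in taken]
        if not pool:
            raise ValueError("diversity pool exhausted while sampling family parents")
        return str(pool[rng.integers(len(pool))])

    if design.families:
        taken: set[str] = set()
        common = design.common_parent
        if common is None:
            common = design.families[0].parent_a
        common = _resolve(common, taken)
        taken.add(common)
        for fam in design.families:
            pa = fam.parent_a if fam.parent_a is not None else common
            if pa not in div_haps:
                raise KeyError(f"unknown parent line id: {pa}")
            pb = _resolve(fam.parent_b, taken)
            taken.add(pb)
            f1 = np.stack([
                _gamete(div_haps[pa], blocks, rng),
                _gamete(div_haps[pb], blocks, rng),
            ])
            for j in range(fam.n_progeny):
                g = int(rng.choice(gens))
                ind = _self_chain(f1, g, blocks, rng)
                hap_list.append(ind)
                ids.append(f"{fam.family_id}_{j + 1:03d}")
                groups.append(fam.family_id)
                sgens.append(g)

    haplotypes = np.stack(hap_list)
    line_ids = np.array(ids, dtype=object)
    membership = pd.Series(groups, index=pd.Index(ids, name="line_id"), name="group")
    return Population(loci, qtl_mask, haplotypes, line_ids, membership,
                      np.array(sgens, dtype=np.int64))


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    population: Population,
    qtl: QTLModel | None,
    trial: TrialDesign,
    seed: int | np.random.Generator,
    trait: str = "trait",
) -> PhenotypeRecords:
    """Per-location entry means y_ij = mu + l_j + g_i + e_ij.

    g_i is the additive QTL value, rescaled (plus an infinitesimal
    polygenic term per ``trial.polygenic_fraction``) so the entry-mean
    heritability sigma_G^2 / (sigma_G^2 + sigma_e^2 / L) matches
    ``trial.target_h2``, with L the harmonic-mean location count.  With
    ``target_h2=None`` the raw QTL values are used untouched.  Location
    effects l_j ~ N(0, location_effect_sd²) and residuals (which absorb
    genotype × location interaction) e_ij ~ N(0, gxe_plus_error_sd²).
    """
    rng = np.random.default_rng(seed)
    n = population.n_lines
    q = (population.qtl_dosages() @ qtl.effects) if (qtl is not None and qtl.n_qtl) else np.zeros(n)

    counts = rng.choice(trial.locations_per_line, size=n)
    l_harm = 1.0 / np.mean(1.0 / counts)

    if trial.target_h2 is None:
        g = q
        sg2_target = float(np.var(q))
    else:
        if trial.gxe_plus_error_sd <= 0:
            raise ValueError("target_h2 calibration needs gxe_plus_error_sd > 0; "
                             "use target_h2=None for noiseless traits")
        h2 = trial.target_h2
        sg2_target = h2 / (1.0 - h2) * trial.gxe_plus_error_sd**2 / l_harm if h2 < 1 else np.inf
        if not np.isfinite(sg2_target):
            raise ValueError("target_h2=1 is only attainable with zero error; use None")
        var_q = float(np.var(q))
        pf = trial.polygenic_fraction if var_q > 0 else 1.0
        qs = (q - q.mean()) * math.sqrt((1 - pf) * sg2_target / var_q) if var_q > 0 else 0.0
        poly = rng.normal(0.0, math.sqrt(pf * sg2_target), size=n) if pf > 0 else 0.0
        g = qs + poly

    loc_effects = rng.normal(0.0, trial.location_effect_sd, size=trial.n_locations_total)
    rows_line, rows_loc, rows_y = [], [], []
    for i in range(n):
        locs = rng.choice(trial.n_locations_total, size=counts[i], replace=False)
        e = rng.normal(0.0, trial.gxe_plus_error_sd, size=counts[i])
        for j, eij in zip(locs, e):
            rows_line.append(population.line_ids[i])
            rows_loc.append(f"LOC_{j + 1}")
            rows_y.append(trial.mu + loc_effects[j] + g[i] + eij)
    df = pd.DataFrame({"line_id": rows_line, "location_id": rows_loc, "value": rows_y})
    truth = {
        "genetic_values": pd.Series(np.asarray(g, dtype=float) if np.ndim(g) else np.full(n, g),
                                    index=population.line_ids),
        "location_effects": loc_effects,
        "sigma2_G_target": sg2_target,
        "sigma2_e": trial.gxe_plus_error_sd**2,
        "L_harmonic": l_harm,
        "mu": trial.mu,
    }
    return PhenotypeRecords(df, trait=trait, truth=truth)


# ---------------------------------------------------------------------------
# adversarial linkage-phase scenario


def flip_linkage_phase(
    population: Population,
    qtl: QTLModel,
    family_id: str,
    window_cM: float = 10.0,
) -> Population:
    """Reverse marker-QTL linkage phase within one family.

    For every QTL, all observed markers within ``window_cM`` on the same
    chromosome are re-coded (allele swap, X -> 2 - X) for the members of
    ``family_id`` only.  QTL genotypes — hence genetic values — are
    untouched; only the family's marker-QTL association changes sign.
    Applying the flip twice restores the original population.
    """
    if family_id not in set(population.membership):
        raise KeyError(f"unknown family: {family_id}")
    if qtl.n_qtl == 0:
        return population
    loci = population.loci
    flank = np.zeros(loci.n_markers, dtype=bool)
    for c, p in zip(qtl.chromosomes, qtl.positions):
        flank |= (loci.chromosomes == c) & (np.abs(loci.positions - p) <= window_cM)
    flank &= ~population.qtl_mask
    if not flank.any():
        return population
    rows = population.lines_in(family_id)
    dos = population.haplotypes[np.ix_(rows, [0, 1], np.flatnonzero(flank))]
    if np.all(dos.sum(axis=1).var(axis=0) == 0):
        raise ValueError(f"{family_id} is monomorphic at every flanking marker; "
                         "phase flip is undefined")
    haps = population.haplotypes.copy()
    sub = haps[np.ix_(rows, [0, 1], np.flatnonzero(flank))]
    haps[np.ix_(rows, [0, 1], np.flatnonzero(flank))] = 1 - sub
    return replace(population, haplotypes=haps)


# ---------------------------------------------------------------------------
# one-call study generator


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_study`."""

    population: Population
    qtl: QTLModel
    phenotypes: dict[str, PhenotypeRecords]

    def marker_matrix(self) -> MarkerMatrix:
        return self.population.marker_matrix()


def simulate_study(
    seed: int,
    design: PopulationDesign | None = None,
    n_chromosomes: int = 9,
    n_markers: int = 677,
    total_length_cM: float = 698.0,
    max_gap_cM: float = 23.0,
    n_founders: int = 8,
    maf_range: tuple[float, float] = (0.1, 0.5),
    n_qtl: int = 30,
    trial: TrialDesign | None = None,
    traits: dict[str, float] | None = None,
) -> SimulatedStudy:
    """Simulate a complete study: map, founders, population, phenotypes.

    Defaults emulate the reference layout (924 lines, 677 markers on a
    698 cM nine-chromosome map with max gap 23 cM, testcrosses at 1-7
    locations, six traits with entry-mean heritabilities 0.38-0.71).
    ``traits`` maps trait name -> target h²; defaults to
    :data:`TRAIT_TARGET_H2`.
    """
    rng = np.random.default_rng(seed)
    design = design or PopulationDesign()
    trial = trial or TrialDesign()
    traits = traits if traits is not None else dict(TRAIT_TARGET_H2)

    gmap = simulate_map(n_chromosomes, n_markers, total_length_cM, max_gap_cM, rng)
    qtl = draw_qtl(gmap, n_qtl, rng)
    loci, qtl_mask, qtl_cols = _merge_loci(gmap, qtl)
    # re-anchor QTL to the combined map: qtl_dosages() yields columns in
    # map order, so effects are permuted to match
    qtl = QTLModel(loci.chromosomes[qtl_mask], loci.positions[qtl_mask],
                   qtl.effects[np.argsort(qtl_cols)])
    founders = simulate_founders(n_founders, loci, maf_range, rng)
    pop = make_population(design, founders, loci, rng, qtl_mask=qtl_mask)
    phenos = {
        name: simulate_phenotypes(pop, qtl, replace(trial, target_h2=h2), rng, trait=name)
        for name, h2 in traits.items()
    }
    return SimulatedStudy(pop, qtl, phenos)
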