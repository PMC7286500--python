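"""Synthetic pedigreed, genotyped, multi-site progeny trials.

Two trial designs are emulated, mirroring the structure of long-running
conifer progeny tests in British Columbia:

* a **full-sib** design: a partial diallel over 54 parents producing 37
  crossed families (~1,300 trees over 3 sites, low effective size), and
* an **open-pollinated half-sib** design: 25 seed-parent families whose
  pollen parents are drawn from a large pollen cloud and recorded as unknown
  in the pedigree (~1,100 trees over 3 sites, high effective size).

Founders are simulated in linkage equilibrium: the trials' wide-cross,
undomesticated background gives no detectable population-wide marker-QTL LD,
so all disequilibrium that genomic prediction can exploit is generated
within families by co-inheritance of large chromosome segments. Meiosis
follows a Haldane (no-interference) model on a ~2,000 cM map.

The phenotype is a single polygenic trait built from the variance components
of the trial mixed models: additive (from explicit QTLs, rescaled to hit the
target additive variance exactly), site x additive, block-within-site,
site x family, family, and residual effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap, make_genetic_map
from .pedigree import (
    ContributionVector,
    PedigreeTable,
    RelationshipMatrix,
    build_numerator_relationship,
    status_number,
)
from .varcomp import VarianceComponents

__all__ = [
    "FounderPool",
    "MatingDesign",
    "Population",
    "TraitArchitecture",
    "TrialData",
    "simulate_founders",
    "make_gamete",
    "simulate_population",
    "simulate_phenotypes",
    "simulate_trial",
    "mendelian_violations",
    "realized_parental_contributions",
    "effective_status_number",
    "default_variance_components",
]

# Default variance targets: mid-range narrow-sense heritability
# (h2 = 2 / 9.5 ~ 0.21 under the full-sib formula), typical of height
# in conifer progeny trials. The trials' own component values are not
# published, so these are generic but realistic choices.
_DEFAULT_VC_FULLSIB = VarianceComponents(
    sigma2_a=2.0, sigma2_sa=1.0, sigma2_srep=0.5, sigma2_sf=0.5, sigma2_f=0.5, sigma2_e=5.5
)
_DEFAULT_VC_HALFSIB = VarianceComponents(
    sigma2_a=2.0, sigma2_sa=1.0, sigma2_srep=0.5, sigma2_sf=0.0, sigma2_f=0.0, sigma2_e=5.5
)


def default_variance_components(kind: str) -> VarianceComponents:
    """Default generative variance components for a design kind."""
    if kind == "full-sib":
        return _DEFAULT_VC_FULLSIB
    if kind == "half-sib":
        return _DEFAULT_VC_HALFSIB
    raise ValueError(f"unknown design kind {kind!r}")


@dataclass(frozen=True)
class FounderPool:
    """Phased founder haplotypes in linkage equilibrium."""

    haplotypes: np.ndarray  # (n_founders, 2, n_markers) int8 in {0,1}
    freqs: np.ndarray  # per-marker allele-1 frequency used for the draw

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.int8)
        object.__setattr__(self, "haplotypes", h)
        if h.ndim != 3 or h.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_founders, 2, n_markers)")
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def realized_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


@dataclass(frozen=True)
class MatingDesign:
    """Crossing layout for one trial.

    ``full-sib``: ``n_families`` pairs are drawn from the first ``n_parents``
    founders by a seeded Polya-urn partial diallel (``urn_alpha`` controls
    parent reuse; smaller = more concentrated contributions and lower status
    number), or an explicit ``crossing_plan`` of (sire_index, dam_index)
    pairs may be given.

    ``half-sib``: the first ``n_families`` founders are seed parents (dams);
    each offspring's pollen parent is drawn uniformly from the next
    ``pollen_pool_size`` founders and recorded as *unknown* in the pedigree.
    """

    kind: str
    n_families: int
    offspring_per_family: int
    n_sites: int = 3
    blocks_per_site: int = 10
    n_parents: int = 54
    pollen_pool_size: int = 500
    urn_alpha: float = 1.1
    crossing_plan: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("full-sib", "half-sib"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.n_families < 1 or self.offspring_per_family < 1:
            raise ValueError("need at least one family with at least one offspring")
        if self.n_sites < 1 or self.blocks_per_site < 1:
            raise ValueError("need at least one site and one block")
        if self.kind == "full-sib" and self.n_parents < 2:
            raise ValueError("full-sib design needs at least two parents")
        if self.kind == "half-sib" and self.pollen_pool_size < 1:
            raise ValueError("half-sib design needs a non-empty pollen pool")

    @property
    def n_founders_required(self) -> int:
        if self.kind == "full-sib":
            return self.n_parents
        return self.n_families + self.pollen_pool_size

    @property
    def n_offspring(self) -> int:
        return self.n_families * self.offspring_per_family


@dataclass(frozen=True)
class Population:
    """A simulated trial: pedigree, phased genotypes and field layout.

    Individuals are ordered founders-first, matching the pedigree order.
    ``realized_sire`` records the true pollen parent even where the pedigree
    says unknown; it backs Mendelian checks and status-number estimation.
    """

    ids: list
    sires: list  # recorded pedigree ("0" = unknown)
    dams: list
    realized_sires: list  # truth; equals sires for full-sib designs
    haplotypes: np.ndarray  # (n_individuals, 2, n_markers) int8
    meta: pd.DataFrame  # offspring rows: id, family, site, block
    gmap: GeneticMap
    founder_freqs: np.ndarray
    n_founders: int
    design: MatingDesign
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {i: k for k, i in enumerate(self.ids)})

    @property
    def founder_ids(self) -> list:
        return self.ids[: self.n_founders]

    @property
    def offspring_ids(self) -> list:
        return self.ids[self.n_founders :]

    def pedigree_table(self) -> PedigreeTable:
        return PedigreeTable(list(self.ids), list(self.sires), list(self.dams))

    def indices(self, ids) -> np.ndarray:
        return np.array([self._index[i] for i in ids], dtype=np.int64)

    def dosages(self, ids=None, marker_indices=None) -> np.ndarray:
        """Genotype dosage matrix (0/1/2 copies of allele 1)."""
        rows = self.indices(ids) if ids is not None else slice(None)
        d = self.haplotypes[rows].sum(axis=1, dtype=np.int8)
        if marker_indices is not None:
            d = d[:, marker_indices]
        return d

    def offspring_dosages(self, marker_indices=None) -> np.ndarray:
        return self.dosages(self.offspring_ids, marker_indices)


@dataclass
class TraitArchitecture:
    """Polygenic additive architecture plus the non-genetic variance targets.

    ``scaling`` is filled by :func:`simulate_phenotypes`: raw N(0,1) QTL
    effects are multiplied by one constant so the realized additive variance
    across offspring equals ``vc.sigma2_a`` exactly.
    """

    qtl_indices: np.ndarray
    raw_effects: np.ndarray
    vc: VarianceComponents
    exclude_qtl_from_panel: bool = True
    sa_structure: str = "additive"  # "additive" (A within site) or "iid"
    mean: float = 10.0
    site_effects: np.ndarray | None = None
    scaling: float | None = None

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.raw_effects = np.asarray(self.raw_effects, dtype=float)
        if self.qtl_indices.size != np.unique(self.qtl_indices).size:
            raise ValueError("QTL indices must be unique")
        if self.qtl_indices.size != self.raw_effects.size:
            raise ValueError("need one raw effect per QTL")
        if self.sa_structure not in ("additive", "iid"):
            raise ValueError("sa_structure must be 'additive' or 'iid'")

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_indices.size)

    @classmethod
    def random(
        cls,
        gmap: GeneticMap,
        n_qtl: int,
        vc: VarianceComponents,
        seed: int,
        **kwargs,
    ) -> "TraitArchitecture":
        """Draw QTL positions uniformly from the map, effects ~ N(0,1)."""
        if n_qtl < 1 or n_qtl > gmap.n_markers:
            raise ValueError("n_qtl must be in [1, n_markers]")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(gmap.n_markers, size=n_qtl, replace=False))
        eff = rng.standard_normal(n_qtl)
        return cls(idx, eff, vc, **kwargs)

    def panel_indices(self, gmap: GeneticMap) -> np.ndarray:
        """Observable SNP panel: all mapped loci minus the QTLs (default)."""
        if not self.exclude_qtl_from_panel:
            return np.arange(gmap.n_markers)
        mask = np.ones(gmap.n_markers, dtype=bool)
        mask[self.qtl_indices] = False
        return np.nonzero(mask)[0]


def simulate_founders(
    n_founders: int, gmap: GeneticMap, maf_min: float, seed: int
) -> FounderPool:
    """Unrelated founders in linkage equilibrium.

    Per-marker allele frequency ~ Uniform[maf_min, 1 - maf_min]; alleles are
    sampled independently per marker and haplotype. Markers that come out
    monomorphic are redrawn so every marker segregates among the founders.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be positive")
    if not 0.0 < maf_min <= 0.5:
        raise ValueError("maf_min must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    freqs = rng.uniform(maf_min, 1.0 - maf_min, size=m)
    haps = (rng.random((n_founders, 2, m)) < freqs).astype(np.int8)
    # redraw monomorphic columns (possible at small n_founders)
    while True:
        counts = haps.sum(axis=(0, 1))
        bad = np.nonzero((counts == 0) | (counts == 2 * n_founders))[0]
        if bad.size == 0:
            break
        haps[:, :, bad] = (
            rng.random((n_founders, 2, bad.size)) < freqs[bad]
        ).astype(np.int8)
    return FounderPool(haps, freqs)


def make_gamete(parent_haplotypes: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """One recombinant gamete from a parent's two phased haplotypes.

    Per chromosome the crossover count is Poisson(length/100) with uniform
    crossover positions (Haldane model, no interference); the starting
    haplotype is chosen with probability 1/2 and the gamete is the resulting
    mosaic of the two parental haplotypes.
    """
    haps = np.asarray(parent_haplotypes)
    if haps.ndim != 2 or haps.shape[0] != 2 or haps.shape[1] != gmap.n_markers:
        raise ValueError("parent haplotypes must have shape (2, n_markers)")
    gamete = np.empty(gmap.n_markers, dtype=haps.dtype)
    for c, sl in enumerate(gmap.chromosome_slices()):
        length = gmap.chrom_lengths[c]
        pos = gmap.pos_cm[sl]
        n_xo = rng.poisson(length / 100.0)
        xo = np.sort(rng.uniform(0.0, length, n_xo))
        start = int(rng.integers(2))
        phase = (start + np.searchsorted(xo, pos)) % 2
        block = haps[:, sl]
        gamete[sl] = np.where(phase == 0, block[0], block[1])
    return gamete


def _interval_recomb_fractions(gmap: GeneticMap) -> list:
    """Per chromosome: Haldane recombination fraction between adjacent markers."""
    out = []
    for sl in gmap.chromosome_slices():
        d = np.diff(gmap.pos_cm[sl]) / 100.0
        out.append(0.5 * (1.0 - np.exp(-2.0 * d)))
    return out


def _gametes_batch(haps: np.ndarray, k: int, gmap: GeneticMap, rfracs, rng) -> np.ndarray:
    """k gametes from one parent, vectorized across gametes and markers.

    Uses the independence of crossover-count parities across marker
    intervals under the no-interference model: the phase switches between
    adjacent markers are independent Bernoulli draws at the Haldane
    recombination fraction, which gives exactly the same marker-level law as
    explicit Poisson crossover placement.
    """
    m = gmap.n_markers
    out = np.empty((k, m), dtype=haps.dtype)
    for sl, r in zip(gmap.chromosome_slices(), rfracs):
        mc = sl.stop - sl.start
        start = rng.integers(2, size=(k, 1))
        if mc > 1:
            switches = rng.random((k, mc - 1)) < r
            phase = (start + np.concatenate(
                [np.zeros((k, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
            )) % 2
        else:
            phase = start % 2
        block = haps[:, sl]
        out[:, sl] = np.where(phase == 0, block[0], block[1])
    return out


def _draw_crossing_plan(design: MatingDesign, rng) -> list:
    """Polya-urn partial diallel: parents are reused preferentially.

    Draw probability for a parent is proportional to (times used +
    urn_alpha), so small urn_alpha concentrates contributions on few
    parents. Repeated pairs are rejected and redrawn.
    """
    if design.crossing_plan is not None:
        plan = [tuple(p) for p in design.crossing_plan]
        for s, d in plan:
            if not (0 <= s < design.n_parents and 0 <= d < design.n_parents):
                raise ValueError(f"crossing plan references absent founder ({s}, {d})")
            if s == d:
                raise ValueError("selfing is not part of these trial designs")
        return plan
    counts = np.zeros(design.n_parents)
    plan: list = []
    used = set()
    for _ in range(design.n_families):
        for _attempt in range(1000):
            w = counts + design.urn_alpha
            p1 = int(rng.choice(design.n_parents, p=w / w.sum()))
            w2 = w.copy()
            w2[p1] = 0.0
            p2 = int(rng.choice(design.n_parents, p=w2 / w2.sum()))
            pair = (min(p1, p2), max(p1, p2))
            if pair not in used:
                break
        else:  # pragma: no cover - essentially impossible at sane sizes
            raise RuntimeError("could not draw a new parent pair")
        used.add(pair)
        plan.append(pair)
        counts[pair[0]] += 1
        counts[pair[1]] += 1
    return plan


def simulate_population(
    founders: FounderPool, design: MatingDesign, gmap: GeneticMap, seed: int
) -> Population:
    """Gene-drop the founders through the mating design.

    Offspring are assigned to sites and blocks by a balanced deterministic
    round-robin, so every family is spread evenly over sites. Deterministic
    given ``seed``.
    """
    if founders.n_markers != gmap.n_markers:
        raise ValueError("founder haplotypes do not match the map")
    if founders.n_founders < design.n_founders_required:
        raise ValueError(
            f"design requires {design.n_founders_required} founders, "
            f"pool has {founders.n_founders}"
        )
    rng = np.random.default_rng(seed)
    rfracs = _interval_recomb_fractions(gmap)
    nf = founders.n_founders
    n_off = design.n_offspring
    founder_ids = [f"P{i + 1:03d}" for i in range(nf)]
    off_width = max(4, len(str(n_off)))
    off_ids = [f"T{i + 1:0{off_width}d}" for i in range(n_off)]

    haplotypes = np.empty((nf + n_off, 2, gmap.n_markers), dtype=np.int8)
    haplotypes[:nf] = founders.haplotypes

    sires: list = ["0"] * nf
    dams: list = ["0"] * nf
    realized: list = ["0"] * nf
    fam_labels = np.empty(n_off, dtype=object)

    fam_width = max(2, len(str(design.n_families)))
    row = nf
    if design.kind == "full-sib":
        plan = _draw_crossing_plan(design, rng)
        for fam, (si, di) in enumerate(plan):
            k = design.offspring_per_family
            g_sire = _gametes_batch(haplotypes[si], k, gmap, rfracs, rng)
            g_dam = _gametes_batch(haplotypes[di], k, gmap, rfracs, rng)
            haplotypes[row : row + k, 0] = g_sire
            haplotypes[row : row + k, 1] = g_dam
            sires += [founder_ids[si]] * k
            dams += [founder_ids[di]] * k
            realized += [founder_ids[si]] * k
            fam_labels[row - nf : row - nf + k] = f"F{fam + 1:0{fam_width}d}"
            row += k
    else:
        pool_lo = design.n_families
        pool_hi = design.n_families + design.pollen_pool_size
        for fam in range(design.n_families):
            di = fam
            k = design.offspring_per_family
            g_dam = _gametes_batch(haplotypes[di], k, gmap, rfracs, rng)
            sire_idx = rng.integers(pool_lo, pool_hi, size=k)
            g_sire = np.empty((k, gmap.n_markers), dtype=np.int8)
            for s in np.unique(sire_idx):
                sel = np.nonzero(sire_idx == s)[0]
                g_sire[sel] = _gametes_batch(haplotypes[s], sel.size, gmap, rfracs, rng)
            haplotypes[row : row + k, 0] = g_sire
            haplotypes[row : row + k, 1] = g_dam
            sires += ["0"] * k  # open pollination: pollen parent unrecorded
            dams += [founder_ids[di]] * k
            realized += [founder_ids[int(s)] for s in sire_idx]
            fam_labels[row - nf : row - nf + k] = f"F{fam + 1:0{fam_width}d}"
            row += k

    idx = np.arange(n_off)
    site = idx % design.n_sites
    per_site_rank = idx // design.n_sites
    block = per_site_rank % design.blocks_per_site
    meta = pd.DataFrame(
        {
            "id": off_ids,
            "family": fam_labels,
            "site": [f"S{s + 1}" for s in site],
            "block": [f"B{b + 1:02d}" for b in block],
        }
    )
    return Population(
        ids=founder_ids + off_ids,
        sires=sires,
        dams=dams,
        realized_sires=realized,
        haplotypes=haplotypes,
        meta=meta,
        gmap=gmap,
        founder_freqs=np.asarray(founders.freqs, dtype=float),
        n_founders=nf,
        design=design,
    )


def _chol_psd(M: np.ndarray) -> np.ndarray:
    """Cholesky with escalating diagonal jitter for near-singular PSD input."""
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(M + jitter * np.eye(M.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10)
    raise np.linalg.LinAlgError("matrix is not positive semidefinite")


def simulate_phenotypes(pop: Population, arch: TraitArchitecture, seed: int) -> pd.DataFrame:
    """Realize the trial phenotype and every generative component.

    The returned frame holds one row per offspring with the trait value
    ``y`` and the true realized draws (``true_a``, ``true_sa``, ...), so
    moment-based checks can compare realized against target variances.
    Every component is *variance-calibrated*: the realized draws are
    centred and rescaled by one constant each so that their empirical
    variance across offspring equals the target component exactly (the
    additive scaling constant is stored on ``arch.scaling``). This keeps
    each simulated trial's generative truth on target instead of scattered
    by the finite number of families, blocks and sites, which is what a
    parameter-recovery study needs; correlation structure within each
    component is unaffected by the common rescaling.
    """
    vc = arch.vc
    if vc.total("fullsib") <= 0:
        raise ValueError("all variance components are zero: no usable trait")
    rng = np.random.default_rng(seed)
    meta = pop.meta
    n = len(meta)
    sites = sorted(meta["site"].unique())

    def calibrated(values: np.ndarray, target: float, what: str) -> np.ndarray:
        vals = values - values.mean()
        sd = vals.std()
        if sd <= 0:
            raise ValueError(f"{what} draws are constant and cannot be scaled")
        return vals * (np.sqrt(target) / sd)

    # additive values from the QTL panel, exactly rescaled
    if vc.sigma2_a > 0:
        X = pop.offspring_dosages(arch.qtl_indices).astype(float)
        a_raw = X @ arch.raw_effects
        sd = a_raw.std()
        if sd <= 0:
            raise ValueError("additive values are constant; QTLs do not segregate")
        arch.scaling = float(np.sqrt(vc.sigma2_a) / sd)
        a = (a_raw - a_raw.mean()) * arch.scaling
    else:
        arch.scaling = 0.0
        a = np.zeros(n)

    # site x additive deviations
    sa = np.zeros(n)
    if vc.sigma2_sa > 0:
        if arch.sa_structure == "additive":
            A = build_numerator_relationship(pop.pedigree_table())
            obs_idx = A.indices(meta["id"])
            for s in sites:
                rows = np.nonzero((meta["site"] == s).to_numpy())[0]
                As = A.values[np.ix_(obs_idx[rows], obs_idx[rows])]
                L = _chol_psd(As)
                sa[rows] = L @ rng.standard_normal(rows.size)
        else:
            sa = rng.standard_normal(n)
        sa = calibrated(sa, vc.sigma2_sa, "site x additive")

    def grouped_effect(labels: pd.Series, sigma2: float, what: str) -> np.ndarray:
        if sigma2 <= 0:
            return np.zeros(n)
        levels, inv = np.unique(labels.to_numpy(), return_inverse=True)
        if levels.size < 2:
            raise ValueError(f"{what} needs at least two levels to carry variance")
        return calibrated(rng.standard_normal(levels.size)[inv], sigma2, what)

    srep = grouped_effect(meta["site"] + ":" + meta["block"], vc.sigma2_srep, "block")
    sf = grouped_effect(meta["site"] + ":" + meta["family"], vc.sigma2_sf, "site x family")
    f = grouped_effect(meta["family"], vc.sigma2_f, "family")
    e = (
        calibrated(rng.standard_normal(n), vc.sigma2_e, "residual")
        if vc.sigma2_e > 0
        else np.zeros(n)
    )

    if arch.site_effects is None:
        sd_e = np.sqrt(vc.sigma2_e)
        base = np.array([0.0, 0.5 * sd_e, -0.5 * sd_e])
        site_eff = np.resize(base, len(sites))
    else:
        site_eff = np.asarray(arch.site_effects, dtype=float)
        if site_eff.size != len(sites):
            raise ValueError("site_effects length does not match the number of sites")
    site_map = {s: site_eff[k] for k, s in enumerate(sites)}
    fixed = meta["site"].map(site_map).to_numpy()

    out = meta.copy()
    out["y"] = arch.mean + fixed + a + sa + srep + sf + f + e
    out["site_fixed"] = fixed
    out["true_a"] = a
    out["true_sa"] = sa
    out["true_srep"] = srep
    out["true_sf"] = sf
    out["true_f"] = f
    out["true_e"] = e
    return out


@dataclass(frozen=True)
class TrialData:
    """One simulated trial bundled for downstream analysis."""

    population: Population
    architecture: TraitArchitecture
    phenotypes: pd.DataFrame

    @property
    def gmap(self) -> GeneticMap:
        return self.population.gmap

    def panel_dosages(self):
        """(marker_indices, dosage matrix) of the observable SNP panel."""
        idx = self.architecture.panel_indices(self.gmap)
        return idx, self.population.offspring_dosages(idx)


def simulate_trial(
    kind: str = "full-sib",
    *,
    seed: int,
    n_families: int | None = None,
    offspring_per_family: int | None = None,
    n_markers: int = 60_000,
    n_qtl: int = 300,
    n_chromosomes: int = 12,
    total_length_cm: float = 2_000.0,
    maf_min: float = 0.05,
    vc: VarianceComponents | None = None,
    n_parents: int = 54,
    pollen_pool_size: int = 500,
    n_sites: int = 3,
    blocks_per_site: int = 10,
    urn_alpha: float = 1.1,
    sa_structure: str = "additive",
    exclude_qtl_from_panel: bool = True,
) -> TrialData:
    """Simulate a complete trial (map, founders, population, phenotypes).

    Defaults reproduce the two study designs: full-sib = 37 families from 54
    parents (36 offspring each, ~1,332 trees), half-sib = 25 open-pollinated
    families (45 offspring each, ~1,125 trees, pollen pool of 500), both on
    3 sites with 10 blocks per site and a 12-chromosome, 2,000 cM map.
    ``n_markers`` counts mapped loci including the ``n_qtl`` causal ones,
    which are excluded from the observable SNP panel unless requested.
    """
    if kind == "full-sib":
        n_families = 37 if n_families is None else n_families
        offspring_per_family = 36 if offspring_per_family is None else offspring_per_family
    elif kind == "half-sib":
        n_families = 25 if n_families is None else n_families
        offspring_per_family = 45 if offspring_per_family is None else offspring_per_family
    else:
        raise ValueError(f"unknown design kind {kind!r}")
    vc = default_variance_components(kind) if vc is None else vc
    ss = np.random.SeedSequence(seed)
    s_map, s_founders, s_pop, s_arch, s_phen = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    gmap = make_genetic_map(n_chromosomes, total_length_cm, n_markers, s_map)
    design = MatingDesign(
        kind=kind,
        n_families=n_families,
        offspring_per_family=offspring_per_family,
        n_sites=n_sites,
        blocks_per_site=blocks_per_site,
        n_parents=n_parents,
        pollen_pool_size=pollen_pool_size,
        urn_alpha=urn_alpha,
    )
    founders = simulate_founders(design.n_founders_required, gmap, maf_min, s_founders)
    pop = simulate_population(founders, design, gmap, s_pop)
    arch = TraitArchitecture.random(
        gmap,
        n_qtl,
        vc,
        s_arch,
        exclude_qtl_from_panel=exclude_qtl_from_panel,
        sa_structure=sa_structure,
    )
    phen = simulate_phenotypes(pop, arch, s_phen)
    return TrialData(pop, arch, phen)


def mendelian_violations(pop: Population) -> int:
    """Count opposing-homozygote conflicts against the *true* parents.

    Zero for every valid gene-drop: an offspring can never be homozygous
    for an allele a true parent lacks entirely.
    """
    total = 0
    off_rows = pop.indices(pop.offspring_ids)
    dos = pop.haplotypes.sum(axis=1, dtype=np.int8)
    for parents in (pop.realized_sires, pop.dams):
        par = [parents[r] for r in off_rows]
        known = np.array([p != "0" for p in par])
        if not known.any():
            continue
        child = dos[off_rows[known]]
        pidx = pop.indices([p for p in par if p != "0"])
        pd_ = dos[pidx]
        total += int(np.sum((child == 0) & (pd_ == 2)) + np.sum((child == 2) & (pd_ == 0)))
    return total


def realized_parental_contributions(pop: Population) -> ContributionVector:
    """Founder gene contributions to the sampled offspring, using the true
    (realized) parents. Each offspring contributes half its genome per parent."""
    n_off = len(pop.offspring_ids)
    contrib = {fid: 0.0 for fid in pop.founder_ids}
    off_rows = pop.indices(pop.offspring_ids)
    for r in off_rows:
        contrib[pop.realized_sires[r]] += 0.5
        contrib[pop.dams[r]] += 0.5
    values = np.array([contrib[fid] for fid in pop.founder_ids]) / n_off
    return ContributionVector(list(pop.founder_ids), values)


def effective_status_number(pop: Population) -> float:
    """Status number of the sampled offspring's gene pool.

    Founders are unrelated and non-inbred by construction, so the founder
    relationship matrix is the identity and Ns reduces to 1 / sum(c_i^2).
    """
    c = realized_parental_contributions(pop)
    A = RelationshipMatrix(np.eye(len(c.ids)), list(c.ids))
    return status_number(A, c)
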