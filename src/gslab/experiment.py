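"""The marker-density x pedigree-structure experiment.

Randomly sampled SNP sets of increasing size are run through replicated
k-fold RR-BLUP cross-validation against EBV responses, and the resulting
accuracies are summarised per SNP-set total (mean, SD and SE over marker
replicates), together with plateau, doubling-factor and full-/half-sib
ratio statistics. Marker-requirement calculators (10 Ne L and markers/cM)
complete the module.

Cross-validation works in the dual (kernel) form of RR-BLUP: the raw n x n
marker kernel is computed once per SNP set and per-fold training-mean
centring is applied through rank-one corrections, which is algebraically
identical to refitting the centred ridge system per fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .mixedmodel import PedigreeBLUP
from .rrblup import MarkerMatrix, reml_lambda_from_kernel
from .simdata import TrialData, effective_status_number, simulate_trial
from .varcomp import VarianceComponents

__all__ = [
    "ExperimentConfig",
    "AccuracySummary",
    "filter_snps_heterozygosity",
    "sample_marker_sets",
    "gs_cross_validate",
    "summarize",
    "doubling_factor",
    "plateau_threshold",
    "design_accuracy_ratio",
    "markers_meuwissen",
    "marker_density_per_cm",
    "markers_from_density",
    "run_design_experiment",
    "DesignExperimentResult",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid and replication settings for the marker-density experiment."""

    grid: tuple = (200, 500, 1_000, 2_500, 5_000, 10_000, 15_000, 25_000, 50_000)
    marker_reps: int = 10
    cv_folds: int = 10
    cv_repeats: int = 10
    max_het: float = 0.40
    lambda_strategy: object = "reml"  # "reml" or ("fixed", value)
    seed: int = 0

    def __post_init__(self):
        g = tuple(int(v) for v in self.grid)
        object.__setattr__(self, "grid", g)
        if len(set(g)) != len(g) or any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("grid values must be unique and ascending")
        if g[0] <= 0:
            raise ValueError("grid values must be positive")
        if self.marker_reps < 1 or self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("need marker_reps >= 1, cv_folds >= 2, cv_repeats >= 1")
        if not 0.0 < self.max_het <= 1.0:
            raise ValueError("max_het must be in (0, 1]")


def filter_snps_heterozygosity(G, max_het: float) -> np.ndarray:
    """Indices of markers whose observed heterozygote fraction is < max_het.

    The heterozygote fraction is the proportion of dosage-1 genotypes per
    marker; highly heterozygous markers are the classic symptom of paralog
    collapse in conifer genotyping and are dropped.
    """
    if not 0.0 < max_het <= 1.0:
        raise ValueError("max_het must be in (0, 1]")
    X = G.values if isinstance(G, MarkerMatrix) else np.asarray(G)
    het = (X == 1).mean(axis=0)
    return np.nonzero(het < max_het)[0]


def sample_marker_sets(pool: np.ndarray, set_total: int, n_reps: int, seed: int) -> list:
    """n_reps independent uniform without-replacement subsets of the pool."""
    pool = np.asarray(pool)
    if set_total > pool.size:
        raise ValueError(f"set_total {set_total} exceeds pool size {pool.size}")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(pool, size=set_total, replace=False)) for _ in range(n_reps)]


def _fold_indices(n: int, k: int, rng) -> list:
    return np.array_split(rng.permutation(n), k)


def gs_cross_validate(
    ebv: np.ndarray,
    Z,
    folds: int = 10,
    repeats: int = 10,
    lambda_strategy="reml",
    seed: int = 0,
    K0: np.ndarray | None = None,
) -> pd.DataFrame:
    """Replicated k-fold RR-BLUP cross-validation for one marker set.

    Individuals are pooled across sites and randomly partitioned afresh per
    repeat. Per fold, the model is trained on the remaining folds (lambda
    re-estimated by spectral REML on the training fold unless fixed) and
    accuracy is the Pearson correlation r(EBV, GEBV) on the held-out fold.
    ``K0`` may pass a precomputed raw kernel Z Z' to avoid recomputation.
    """
    y = np.asarray(ebv, dtype=float)
    X = Z.values if isinstance(Z, MarkerMatrix) else np.asarray(Z, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("EBV vector and marker matrix do not align")
    if n < 2 * folds:
        raise ValueError("need at least 2 observations per fold")
    if K0 is None:
        K0 = X @ X.T
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        for fold_i, va in enumerate(_fold_indices(n, folds, rng)):
            tr = np.setdiff1d(np.arange(n), va, assume_unique=True)
            c = X[tr].mean(axis=0)
            s = X @ c
            cc = float(c @ c)
            K_tr = K0[np.ix_(tr, tr)] - s[tr][:, None] - s[tr][None, :] + cc
            ytr = y[tr]
            if np.ptp(ytr) == 0 or np.ptp(y[va]) == 0:
                rows.append((rep, fold_i, np.nan, va.size, True))
                continue
            if lambda_strategy == "reml":
                lam, _, _ = reml_lambda_from_kernel(ytr, K_tr)
            else:
                kind, value = lambda_strategy
                if kind != "fixed":
                    raise ValueError("lambda_strategy must be 'reml' or ('fixed', value)")
                lam = float(value)
            mu = ytr.mean()
            try:
                alpha = cho_solve(cho_factor(K_tr + lam * np.eye(tr.size)), ytr - mu)
            except np.linalg.LinAlgError:
                alpha = cho_solve(
                    cho_factor(K_tr + (lam + 1e-8) * np.eye(tr.size)), ytr - mu
                )
            K_va = K0[np.ix_(va, tr)] - s[va][:, None] - s[tr][None, :] + cc
            gebv = K_va @ alpha + mu
            if np.ptp(gebv) == 0:
                rows.append((rep, fold_i, np.nan, va.size, True))
                continue
            acc = float(np.corrcoef(y[va], gebv)[0, 1])
            rows.append((rep, fold_i, acc, va.size, False))
    return pd.DataFrame(rows, columns=["cv_repeat", "fold", "accuracy", "n_validation", "missing"])


@dataclass(frozen=True)
class AccuracySummary:
    """Per-SNP-set-total accuracy statistics over marker replicates.

    ``table`` is indexed by set_total with columns ``mean`` (mean of the
    marker-replicate means), ``sd`` (SD across marker replicates, 0 for a
    single replicate), ``se`` (= sd / sqrt(n_reps)) and ``n_reps``.
    """

    table: pd.DataFrame

    @property
    def grid(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def means(self) -> pd.Series:
        return self.table["mean"]


def summarize(results: pd.DataFrame) -> AccuracySummary:
    """Collapse a tidy CV-result frame into per-set-total statistics.

    Expects columns set_total, marker_rep, accuracy (and missing). The
    replicate-level mean averages all non-missing fold accuracies of that
    marker replicate; mean/SD/SE are then taken over replicate-level means.
    """
    ok = results[~results["missing"]]
    if ok.empty:
        raise ValueError("no non-missing accuracies to summarise")
    rep_means = (
        ok.groupby(["set_total", "marker_rep"])["accuracy"].mean().rename("rep_mean")
    )
    g = rep_means.groupby("set_total")
    table = pd.DataFrame(
        {
            "mean": g.mean(),
            "sd": g.std(ddof=1).fillna(0.0),
            "n_reps": g.size(),
        }
    )
    table["se"] = table["sd"] / np.sqrt(table["n_reps"])
    return AccuracySummary(table[["mean", "sd", "se", "n_reps"]].sort_index())


def doubling_factor(summary: AccuracySummary) -> float:
    """Mean accuracy ratio over all exact (m, 2m) grid pairs."""
    means = summary.means
    grid = set(summary.grid.tolist())
    ratios = [
        means.loc[2 * m] / means.loc[m] for m in sorted(grid) if 2 * m in grid
    ]
    if not ratios:
        raise ValueError(
            "grid contains no (m, 2m) pairs; add doubling pairs to the SNP-set grid"
        )
    return float(np.mean(ratios))


def plateau_threshold(summary: AccuracySummary, rel_tol: float = 0.02) -> int:
    """Smallest SNP-set total within rel_tol of the best mean accuracy."""
    means = summary.means
    cutoff = (1.0 - rel_tol) * means.max()
    hits = means[means >= cutoff]
    return int(hits.index.min())


def design_accuracy_ratio(summary_fullsib: AccuracySummary, summary_halfsib: AccuracySummary):
    """Elementwise full-sib / half-sib mean-accuracy ratio and its grand mean."""
    if not np.array_equal(summary_fullsib.grid, summary_halfsib.grid):
        raise ValueError("summaries were computed on different SNP-set grids")
    per = summary_fullsib.means / summary_halfsib.means
    return per.rename("fs_hs_ratio"), float(per.mean())


def markers_meuwissen(ne: float, L_morgans: float) -> float:
    """Minimum marker count 10 * Ne * L (L in Morgans)."""
    if ne <= 0 or L_morgans <= 0:
        raise ValueError("Ne and L must be positive")
    return 10.0 * ne * L_morgans


def marker_density_per_cm(n_markers: float, L_cm: float) -> float:
    """Average marker density in markers per centimorgan."""
    if n_markers <= 0 or L_cm <= 0:
        raise ValueError("marker count and map length must be positive")
    return float(n_markers) / float(L_cm)


def markers_from_density(density_per_cm: float, L_cm: float) -> float:
    """Marker count implied by a target density on a map of given length."""
    if density_per_cm <= 0 or L_cm <= 0:
        raise ValueError("density and map length must be positive")
    return float(density_per_cm) * float(L_cm)


@dataclass(frozen=True)
class DesignExperimentResult:
    """Everything one design's experiment produced."""

    kind: str
    trial: TrialData
    ebv: pd.Series
    heritability: float
    varcomp: VarianceComponents
    status_number: float
    pool_size: int
    cv: pd.DataFrame
    summary: AccuracySummary


def run_design_experiment(
    kind: str,
    config: ExperimentConfig,
    *,
    seed: int | None = None,
    reml_tol: float = 1e-4,
    reml_maxiter: int = 300,
    **sim_kwargs,
) -> DesignExperimentResult:
    """Simulate one trial design and run the full marker-density experiment.

    Pipeline: simulate the trial; fit the pedigree mixed model by EM-REML
    and extract offspring EBVs; apply the heterozygosity filter to the
    observable SNP panel; draw random marker sets over the grid; run
    replicated k-fold RR-BLUP cross-validation per set; summarise. One
    master seed drives independent child streams for simulation, marker
    sampling and CV partitions, so each stage is reproducible in isolation.
    """
    master = config.seed if seed is None else seed
    sim_seed = int(np.random.SeedSequence([master, 1]).generate_state(1)[0] % 2**31)
    trial = simulate_trial(kind, seed=sim_seed, **sim_kwargs)
    model_kind = "fullsib" if kind == "full-sib" else "halfsib"
    model = PedigreeBLUP(trial.phenotypes, trial.population.pedigree_table(), kind=model_kind)
    fit = model.fit(tol=reml_tol, maxiter=reml_maxiter)
    off_ids = trial.population.offspring_ids
    ebv = fit.ebv.loc[off_ids]

    _, X = trial.panel_dosages()
    keep = filter_snps_heterozygosity(X, config.max_het)
    if config.grid[-1] > keep.size:
        raise ValueError(
            f"largest grid value {config.grid[-1]} exceeds the filtered pool ({keep.size})"
        )
    X = np.ascontiguousarray(X[:, keep], dtype=np.float64)
    y = ebv.to_numpy()

    frames = []
    for gi, set_total in enumerate(config.grid):
        sample_seed = int(
            np.random.SeedSequence([master, 2, gi]).generate_state(1)[0] % 2**31
        )
        subsets = sample_marker_sets(np.arange(keep.size), set_total, config.marker_reps,
                                     sample_seed)
        for ri, idx in enumerate(subsets):
            Zs = X[:, idx]
            K0 = Zs @ Zs.T
            cv_seed = int(
                np.random.SeedSequence([master, 3, gi, ri]).generate_state(1)[0] % 2**31
            )
            cv = gs_cross_validate(
                y, Zs, folds=config.cv_folds, repeats=config.cv_repeats,
                lambda_strategy=config.lambda_strategy, seed=cv_seed, K0=K0,
            )
            cv.insert(0, "marker_rep", ri)
            cv.insert(0, "set_total", set_total)
            frames.append(cv)
    cv_all = pd.concat(frames, ignore_index=True)
    return DesignExperimentResult(
        kind=kind,
        trial=trial,
        ebv=ebv,
        heritability=fit.heritability,
        varcomp=fit.varcomp,
        status_number=effective_status_number(trial.population),
        pool_size=int(keep.size),
        cv=cv_all,
        summary=summarize(cv_all),
    )


def plot_accuracy(summaries: dict, path: str) -> None:
    """Accuracy-vs-marker-number plot (log x) for one or more designs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, summary in summaries.items():
        t = summary.table
        ax.errorbar(t.index, t["mean"], yerr=t["se"], marker="o", capsize=3, label=label)
    ax.set_xscale("log")
    ax.set_xlabel("SNP set total")
    ax.set_ylabel("prediction accuracy r(EBV, GEBV)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
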