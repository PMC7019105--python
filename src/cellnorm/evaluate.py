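"""Quantitative comparison of normalization methods.

The yardstick is downstream class recovery: embed cells with PCA, classify
condition labels with K-nearest neighbours over repeated stratified
train/test splits, and score each repeat with Cohen's kappa -- a
chance-corrected agreement statistic that stays meaningful when group
sizes are unequal.  A Benjamini-Hochberg-screened two-group test counts
detectable differentially expressed genes per method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier

from .config import RunConfig, derive_seed
from .data import CountMatrix, DataError, NormalizedMatrix, clean_counts
from .simulate import simulate_dataset

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "cohens_kappa",
    "knn_classify_repeated",
    "pca_embed",
    "embed_nonlinear",
    "bh_adjust",
    "de_screen",
    "benchmark_run",
]


@dataclass
class ConfusionMatrix:
    """Square table of true (rows) vs predicted (columns) condition counts."""

    counts: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DataError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise DataError("confusion counts must be non-negative")
        if self.counts.sum() == 0:
            raise DataError("confusion matrix is empty")
        if len(self.labels) != self.counts.shape[0]:
            raise DataError("labels length mismatch")

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels: list | None = None) -> "ConfusionMatrix":
        labels = sorted(set(y_true) | set(y_pred)) if labels is None else list(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts, [str(x) for x in labels])


def cohens_kappa(cmx: ConfusionMatrix) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) with chance agreement from margins."""
    counts = cmx.counts.astype(float)
    total = counts.sum()
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        if p_o == 1.0:
            return 1.0
        raise DataError("chance agreement is 1 with imperfect observed agreement")
    return float((p_o - p_e) / (1.0 - p_e))


def knn_classify_repeated(
    values: np.ndarray,
    labels,
    k: int = 5,
    train_fraction: float = 0.7,
    n_repeats: int = 100,
    seed: int = 1,
) -> list[float]:
    """Kappa over repeated stratified splits of a cells x features matrix.

    Euclidean KNN with majority vote (ties resolved toward the smallest
    class index).  Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise DataError("need at least 2 conditions")
    small = classes[counts < k + 1]
    if small.size:
        raise DataError(
            f"condition(s) {small.tolist()} have fewer than k+1={k + 1} cells"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=seed
    )
    label_list = sorted(classes.tolist())
    kappas = []
    for train, test in splitter.split(values, labels):
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(values[train], labels[train])
        pred = clf.predict(values[test])
        cmx = ConfusionMatrix.from_predictions(labels[test], pred, labels=label_list)
        kappas.append(cohens_kappa(cmx))
    return kappas


def pca_embed(values: np.ndarray, n_components: int = 50) -> np.ndarray:
    """Centered-SVD principal component scores of cells.

    ``values`` is genes x cells; the returned scores are cells x
    components, ordered by decreasing singular value, with each
    component's largest-magnitude gene loading made positive.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    if n_components > min(n_genes, n_cells):
        raise DataError(
            f"n_components={n_components} exceeds min(genes, cells)="
            f"{min(n_genes, n_cells)}"
        )
    X = values.T - values.T.mean(axis=0, keepdims=True)  # cells x genes, centered
    if np.allclose(X, 0):
        raise DataError("constant matrix has no principal components")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # sign convention: the largest-|loading| gene of each component is positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    return U * S[None, :] * flip[None, :]


def embed_nonlinear(
    scores: np.ndarray,
    method: str = "tsne",
    n_components: int = 2,
    seed: int = 1,
    **kwargs,
) -> np.ndarray:
    """Optional nonlinear embedding of PCA scores (post-hoc visualization).

    Thin hook over the standard implementations: ``tsne`` uses
    scikit-learn, ``umap`` uses umap-learn (imported lazily; an informative
    error is raised when the library is unavailable).  Input is cells x
    features (typically the output of :func:`pca_embed`).
    """
    scores = np.asarray(scores, dtype=float)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = kwargs.pop("perplexity", min(30.0, max(2.0, scores.shape[0] / 4)))
        return TSNE(
            n_components=n_components, random_state=seed,
            perplexity=perplexity, init="pca", **kwargs,
        ).fit_transform(scores)
    if method == "umap":
        try:
            import umap
        except ImportError as exc:  # pragma: no cover
            raise DataError("umap-learn is not installed") from exc
        return umap.UMAP(
            n_components=n_components, random_state=seed, **kwargs
        ).fit_transform(scores)
    raise DataError("method must be 'tsne' or 'umap'")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataError("p must be 1-D")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def de_screen(
    nm: NormalizedMatrix,
    labels,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> tuple[np.ndarray, int]:
    """Per-gene two-group screen on normalized values with BH control.

    Returns the raw p-values and the number of genes whose BH-adjusted
    p-value is below ``alpha``.  ``wilcoxon`` is the rank-sum test;
    ``nb_wald`` fits a per-gene negative-binomial GLM with a group term
    (intended for linear-scale, count-like values).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise DataError(
            f"de_screen handles exactly 2 conditions (got {groups.size}); "
            "run pairwise comparisons instead"
        )
    a = nm.values[:, labels == groups[0]]
    b = nm.values[:, labels == groups[1]]
    if test == "wilcoxon":
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    elif test == "nb_wald":
        p = _nb_wald_pvalues(a, b)
    else:
        raise DataError("test must be 'wilcoxon' or 'nb_wald'")
    adjusted = bh_adjust(p)
    return p, int(np.sum(adjusted < alpha))


def _nb_wald_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    n_genes = a.shape[0]
    y_group = np.r_[np.zeros(a.shape[1]), np.ones(b.shape[1])]
    design = sm.add_constant(y_group)
    p = np.ones(n_genes)
    for i in range(n_genes):
        y = np.r_[a[i], b[i]]
        if y.max() <= 0 or np.all(y == y[0]):
            continue
        mean, var = y.mean(), y.var(ddof=1)
        alpha_mom = max((var - mean) / mean**2, 1e-8)
        try:
            fit = sm.GLM(
                y, design, family=sm.families.NegativeBinomial(alpha=alpha_mom)
            ).fit()
            p[i] = fit.pvalues[1]
        except Exception:
            p[i] = 1.0
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


@dataclass
class EvaluationReport:
    """Per-method kappa samples plus the settings that produced them."""

    kappas: dict[str, list[float]]
    knn_k: int
    train_fraction: float
    n_repeats: int
    seed: int
    de_counts: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def median_kappa(self, method: str) -> float:
        return float(np.median(self.kappas[method]))

    def to_dict(self) -> dict:
        return {
            "kappas": {m: list(map(float, v)) for m, v in self.kappas.items()},
            "median_kappa": {m: self.median_kappa(m) for m in self.kappas},
            "knn_k": self.knn_k,
            "train_fraction": self.train_fraction,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "de_counts": self.de_counts,
            "skipped": self.skipped,
            "config": self.config,
        }


def evaluation_matrix(nm: NormalizedMatrix, spikein_rows: np.ndarray | None = None) -> np.ndarray:
    """Log-scale gene x cell matrix for embedding/classification.

    Linear-scale outputs are ``ln(x + 1)``-transformed; log-scale outputs
    pass through.  Spike-in rows (given as input-matrix row indices) are
    excluded so only biological signal is evaluated.
    """
    values = nm.values
    keep = np.ones(values.shape[0], dtype=bool)
    if spikein_rows is not None and len(spikein_rows):
        spike = np.isin(nm.kept_gene_index, spikein_rows)
        keep = ~spike
    values = values[keep]
    if nm.scale == "linear":
        values = np.log1p(np.maximum(values, 0.0))
    return values


def benchmark_run(config: RunConfig | dict | None = None, cm: CountMatrix | None = None,
                  truth=None, **overrides) -> EvaluationReport:
    """Simulate (or take) a labelled data set and compare the methods.

    Pipeline: simulate -> clean -> normalize per method (raw counts always
    included as baseline) -> log transform of linear-scale outputs -> PCA
    -> repeated KNN -> per-method kappa distributions (+ optional
    BH-screened DE counts).  Fully seeded and deterministic.
    """
    from . import normalize as norm

    if config is None:
        config = RunConfig(**overrides)
    elif isinstance(config, dict):
        config = RunConfig(**{**config, **overrides})
    seed = config.seed

    if cm is None:
        cm, truth = simulate_dataset(
            n_genes=config.n_genes,
            n_cells_per_group=config.n_cells_per_group,
            fold_change=config.fold_change,
            n_de=config.n_de,
            theta=config.theta,
            n_spikeins=config.n_spikeins,
            seed=derive_seed(seed, "simulate"),
        )
    if cm.condition is None:
        raise DataError("benchmark needs condition labels on the matrix")
    cm = clean_counts(cm, config.min_gene_total, config.min_cell_total)
    labels = np.asarray(cm.condition)
    spike_rows = np.flatnonzero(cm.is_spikein)
    has_spikes = spike_rows.size > 0
    ref = None
    if has_spikes:
        from .simulate import default_spikein_reference
        panel = default_spikein_reference(config.n_spikeins)
        # keep only ids actually present (simulated panels use these ids)
        present = {cm.gene_ids[i] for i in spike_rows}
        if present <= set(panel.ids):
            ref = panel

    normalized: dict[str, NormalizedMatrix] = {}
    skipped: dict[str, str] = {}
    for method in config.methods:
        try:
            if method in norm.SPIKEIN_METHODS and not has_spikes:
                skipped[method] = "requires spike-in rows; none in the data"
                continue
            if method == "basics":
                normalized[method] = _run_basics(cm, config)
            elif method == "grm":
                if ref is None:
                    skipped[method] = "no spike-in concentration reference available"
                    continue
                normalized[method] = norm.normalize_grm(cm, ref)
            elif method == "samstrt":
                normalized[method] = norm.normalize_samstrt(
                    cm, seed=derive_seed(seed, "samstrt")
                )
            elif method == "scran":
                normalized[method] = norm.normalize_scran(cm)
            elif method == "scnorm":
                nm, _ = norm.normalize_scnorm(cm, min_nonzero=config.scnorm_min_nonzero)
                normalized[method] = nm
            elif method == "linnorm":
                nm, _ = norm.normalize_linnorm(cm, c=config.linnorm_c)
                normalized[method] = nm
            elif method == "simple":
                normalized[method] = norm.normalize_simple(cm)
        except DataError as exc:
            skipped[method] = str(exc)

    # raw baseline: untouched counts on the same footing
    raw = NormalizedMatrix(
        values=cm.counts.astype(float),
        method="raw",
        scale="linear",
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
    )
    ordered: dict[str, NormalizedMatrix] = {"raw": raw, **normalized}

    kappas: dict[str, list[float]] = {}
    de_counts: dict[str, int] = {}
    embeddings: dict[str, np.ndarray] = {}
    for method, nm in ordered.items():
        values = evaluation_matrix(nm, spike_rows)
        n_comp = min(config.n_components, values.shape[0], values.shape[1])
        scores = pca_embed(values, n_comp)
        embeddings[method] = scores
        kappas[method] = knn_classify_repeated(
            scores,
            labels,
            k=config.knn_k,
            train_fraction=config.train_fraction,
            n_repeats=config.n_repeats,
            seed=derive_seed(seed, f"knn:{method}"),
        )
        if config.compute_de:
            eval_nm = NormalizedMatrix(
                values=values, method=method, scale="log",
                gene_ids=[f"g{i}" for i in range(values.shape[0])],
                cell_ids=list(nm.cell_ids),
            )
            _, de_counts[method] = de_screen(eval_nm, labels, alpha=config.de_alpha)

    return EvaluationReport(
        kappas=kappas,
        knn_k=config.knn_k,
        train_fraction=config.train_fraction,
        n_repeats=config.n_repeats,
        seed=seed,
        de_counts=de_counts,
        skipped=skipped,
        embeddings=embeddings,
        config=config.to_dict(),
    )


def _run_basics(cm: CountMatrix, config: RunConfig) -> NormalizedMatrix:
    """Fit the Poisson-Gamma model on a high-count gene subset, apply to all."""
    from .normalize import fit_basics, normalize_basics

    bio = np.flatnonzero(~cm.is_spikein)
    if bio.size > config.basics_max_genes:
        totals = cm.counts[bio].sum(axis=1)
        top = bio[np.argsort(totals, kind="stable")[::-1][: config.basics_max_genes]]
        rows = np.sort(np.concatenate([top, np.flatnonzero(cm.is_spikein)]))
        sub = cm.subset(rows, None)
    else:
        sub = cm
    fit = fit_basics(
        sub,
        n_iter=config.basics_n_iter,
        burn_in=config.basics_burn_in,
        thin=config.basics_thin,
        seed=derive_seed(config.seed, "basics"),
    )
    return normalize_basics(fit, cm)
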