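"""Chemoresistance gene-signature selection and patient classification.

Selection: each candidate (double-regulated) gene is tested between resistant
and sensitive patients of a labelled cohort with a two-sided Mann–Whitney U
test; genes with p < 0.10 are retained and their direction is the sign of
(median resistant − median sensitive).  The package ships the published-style
17-gene signature table (``chemosig.signature.load_signature_table``) with
per-gene p-values between 0.004 and 0.094, all passing this filter.

Classifiers (all operating on the signature genes):

* Bayesian binary regression — genes are z-scored with training statistics,
  the training matrix is decomposed by SVD, sample scores on the top-k right
  singular directions ("metagenes") enter a binary probit regression fit by
  maximum a posteriori under a zero-mean Gaussian prior (precision λ = 1) on
  the coefficients, i.e. ridge probit solved by Newton iterations.
* Hierarchical clustering — 1 − Pearson correlation distance between
  patients, average linkage, 2-cluster cut, clusters labelled by majority of
  true labels.
* Nearest centroid ("kNN versus the class-average expression") — each query
  is assigned to the class whose mean z-scored expression vector is closer in
  Euclidean distance; ties go to sensitive.  A literal k-nearest-neighbour
  over reference patients is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io import CohortTable

__all__ = [
    "SignatureModel",
    "ClassificationResult",
    "load_signature_table",
    "filter_signature_table",
    "select_signature",
    "BBRParams",
    "fit_bbr",
    "predict_bbr",
    "hclust_classify",
    "centroid_classify",
    "knn_classify",
]


# ---------------------------------------------------------------------------
# signature table / selection


@dataclass
class SignatureModel:
    """An ordered gene signature with directions and selection p-values."""

    genes: list[str]
    directions: dict[str, str]  # gene → "up"/"down" (in resistant)
    p_values: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g not in self.directions or g not in self.p_values:
                raise ValueError(f"gene {g} missing direction or p-value")

    def __len__(self) -> int:
        return len(self.genes)

    def direction_signs(self) -> pd.Series:
        """+1 for up-in-resistant, −1 for down."""
        return pd.Series({g: 1.0 if self.directions[g] == "up" else -1.0 for g in self.genes})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "direction": [self.directions[g] for g in self.genes],
                "p_value": [self.p_values[g] for g in self.genes],
            }
        )


def load_signature_table(path=None) -> pd.DataFrame:
    """The packaged 17-gene chemoresistance signature table.

    Columns: gene, p_value (per-gene two-group test in the 27-patient TNBC
    training cohort), direction (up/down in resistant patients).
    """
    if path is None:
        ref = resources.files("chemosig.data") / "signature_17gene.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t")
    return pd.read_csv(path, sep="\t")


def filter_signature_table(table: pd.DataFrame, p_max: float = 0.10) -> SignatureModel:
    """Apply the selection filter (p < p_max) to a signature-style table."""
    kept = table[table["p_value"] < p_max]
    genes = list(kept["gene"])
    return SignatureModel(
        genes,
        dict(zip(kept["gene"], kept["direction"])),
        dict(zip(kept["gene"], kept["p_value"])),
    )


def select_signature(
    candidate_genes: list[str],
    cohort: CohortTable,
    p_max: float = 0.10,
    test: str = "mannwhitney",
    require_concordance: dict[str, str] | None = None,
) -> SignatureModel:
    """Select signature genes from candidates against a labelled cohort.

    Per gene: two-sided Mann–Whitney U (or Welch t with ``test="ttest"``) of
    expression between resistant and sensitive patients; retain p < p_max.
    Direction = sign of (median resistant − median sensitive).  Candidates
    absent from the cohort columns are skipped with a warning entry.
    ``require_concordance`` ({gene: expected direction}) optionally drops
    genes whose cohort direction contradicts an expected one (off by default).
    """
    labels = cohort.labels
    res = cohort.table[labels == "resistant"]
    sen = cohort.table[labels == "sensitive"]
    if len(res) < 2 or len(sen) < 2:
        raise ValueError("need at least two patients per class")
    genes, dirs, ps, warnings = [], {}, {}, []
    for g in candidate_genes:
        if g not in cohort.table.columns:
            warnings.append(f"candidate {g} absent from cohort columns; skipped")
            continue
        xr = res[g].to_numpy(dtype=float)
        xs = sen[g].to_numpy(dtype=float)
        if test == "mannwhitney":
            p = float(stats.mannwhitneyu(xr, xs, alternative="two-sided").pvalue)
        elif test == "ttest":
            p = float(stats.ttest_ind(xr, xs, equal_var=False).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        direction = "up" if np.median(xr) - np.median(xs) > 0 else "down"
        if p < p_max:
            if require_concordance and require_concordance.get(g, direction) != direction:
                warnings.append(f"candidate {g} direction discordant; dropped")
                continue
            genes.append(g)
            dirs[g] = direction
            ps[g] = p
    return SignatureModel(genes, dirs, ps, warnings)


# ---------------------------------------------------------------------------
# classification results


@dataclass
class ClassificationResult:
    patient_id: str
    predicted: str  # sensitive / resistant
    probability_resistant: float | None  # regression method only
    method: str


def _accuracy(results: list[ClassificationResult], labels: pd.Series) -> float:
    hits = sum(1 for r in results if labels.get(r.patient_id) == r.predicted)
    return hits / len(results)


# ---------------------------------------------------------------------------
# Bayesian binary regression (SVD metagenes + MAP probit)


@dataclass
class BBRParams:
    genes: list[str]
    mean: np.ndarray  # training per-gene means
    sd: np.ndarray  # training per-gene SDs (ddof=1)
    loadings: np.ndarray  # genes × k right singular vectors
    coef: np.ndarray  # probit coefficients, [intercept, k metagenes]
    n_metagenes: int
    prior_precision: float
    n_iter: int


def _zscore(expr: pd.DataFrame, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (expr.to_numpy(dtype=float) - mean) / sd


def _probit_map(
    X: np.ndarray, y: np.ndarray, prior_precision: float, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, int]:
    """Ridge-probit MAP by Newton (Fisher scoring); raises on non-convergence."""
    n, p = X.shape
    beta = np.zeros(p)
    lam = prior_precision
    for it in range(1, max_iter + 1):
        eta = X @ beta
        phi = stats.norm.pdf(eta)
        Phi = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        # gradient of the log-posterior
        g_obs = np.where(y == 1, phi / Phi, -phi / (1 - Phi))
        grad = X.T @ g_obs - lam * beta
        w = phi**2 / (Phi * (1 - Phi))  # expected information weights
        H = X.T @ (X * w[:, None]) + lam * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.linalg.norm(step) < tol:
            return beta, it
    raise RuntimeError(f"probit MAP did not converge in {max_iter} iterations")


def fit_bbr(
    cohort: CohortTable,
    genes: list[str] | None = None,
    n_metagenes: int | None = None,
    prior_precision: float = 1.0,
    max_metagenes: int = 3,
    variance_target: float = 0.90,
) -> BBRParams:
    """Fit the SVD-metagene probit classifier on a labelled cohort.

    ``n_metagenes`` defaults to the smallest k explaining ≥ ``variance_target``
    of the z-scored training variance, capped at ``max_metagenes`` and at
    min(#patients − 1, #genes).
    """
    genes = list(genes) if genes is not None else cohort.genes
    missing = [g for g in genes if g not in cohort.table.columns]
    if missing:
        raise ValueError(f"cohort missing gene columns {missing}")
    expr = cohort.table[genes]
    labels = cohort.labels
    if set(labels) - {"sensitive", "resistant"}:
        raise ValueError("training cohort must be fully labelled")
    y = (labels == "resistant").to_numpy(dtype=float)
    mean = expr.to_numpy(dtype=float).mean(axis=0)
    sd = expr.to_numpy(dtype=float).std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(f"constant expression for genes {bad}")
    Z = _zscore(expr, mean, sd)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k_cap = min(len(cohort.patient_ids) - 1, len(genes))
    if n_metagenes is None:
        var = S**2 / (S**2).sum()
        k = int(np.searchsorted(np.cumsum(var), variance_target) + 1)
        k = min(k, max_metagenes, k_cap)
    else:
        k = n_metagenes
    if k < 1 or k > k_cap:
        raise ValueError(f"n_metagenes={k} outside [1, {k_cap}]")
    loadings = Vt[:k].T  # genes × k
    scores = Z @ loadings
    X = np.column_stack([np.ones(len(y)), scores])
    coef, n_iter = _probit_map(X, y, prior_precision)
    return BBRParams(genes, mean, sd, loadings, coef, k, prior_precision, n_iter)


def predict_bbr(params: BBRParams, expression: pd.DataFrame) -> list[ClassificationResult]:
    """Project new samples with training loadings; threshold Φ(η) at 0.5."""
    missing = [g for g in params.genes if g not in expression.columns]
    if missing:
        raise ValueError(f"expression missing gene columns {missing}")
    Z = _zscore(expression[params.genes], params.mean, params.sd)
    scores = Z @ params.loadings
    eta = params.coef[0] + scores @ params.coef[1:]
    prob = stats.norm.cdf(eta)
    return [
        ClassificationResult(
            patient_id=str(pid),
            predicted="resistant" if p >= 0.5 else "sensitive",
            probability_resistant=float(p),
            method="bbr",
        )
        for pid, p in zip(expression.index, prob)
    ]


def bbr_accuracy(cohort: CohortTable, genes: list[str] | None = None, **kwargs) -> float:
    """In-sample accuracy of the probit metagene classifier."""
    params = fit_bbr(cohort, genes=genes, **kwargs)
    results = predict_bbr(params, cohort.table[params.genes])
    return _accuracy(results, cohort.labels)


# ---------------------------------------------------------------------------
# hierarchical clustering


def hclust_classify(
    cohort: CohortTable,
    genes: list[str] | None = None,
    directions: dict[str, str] | None = None,
) -> tuple[list[ClassificationResult], float, np.ndarray]:
    """Correlation-distance average-linkage clustering into two labelled clusters.

    Each of the two clusters takes the majority of its members' true labels;
    on a tie, the cluster containing the patient with the highest mean
    resistant-direction score (direction-signed z-scored expression) is
    labelled resistant.  Returns (results, accuracy, linkage matrix).
    """
    genes = list(genes) if genes is not None else cohort.genes
    expr = cohort.table[genes].to_numpy(dtype=float)
    sds = expr.std(axis=1)
    if np.any(sds == 0):
        bad = [pid for pid, s in zip(cohort.patient_ids, sds) if s == 0]
        raise ValueError(f"constant expression vector for patients {bad}")
    corr = np.corrcoef(expr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    assignment = fcluster(linkage, t=2, criterion="maxclust")
    labels = cohort.labels
    # direction-signed score per patient, for the tie-break
    col_mean = expr.mean(axis=0)
    col_sd = expr.std(axis=0, ddof=1)
    col_sd[col_sd == 0] = 1.0
    z = (expr - col_mean) / col_sd
    if directions is None:
        signs = np.ones(len(genes))
    else:
        signs = np.array([1.0 if directions.get(g, "up") == "up" else -1.0 for g in genes])
    res_score = (z * signs).mean(axis=1)
    cluster_label: dict[int, str] = {}
    tie_clusters = []
    for c in np.unique(assignment):
        members = labels[assignment == c]
        n_res = int((members == "resistant").sum())
        n_sen = int((members == "sensitive").sum())
        if n_res > n_sen:
            cluster_label[c] = "resistant"
        elif n_sen > n_res:
            cluster_label[c] = "sensitive"
        else:
            tie_clusters.append(c)
    if tie_clusters:
        best_patient = int(np.argmax(res_score))
        res_cluster = assignment[best_patient]
        for c in np.unique(assignment):
            if c not in cluster_label:
                cluster_label[c] = "resistant" if c == res_cluster else "sensitive"
    results = [
        ClassificationResult(str(pid), cluster_label[c], None, "hclust")
        for pid, c in zip(cohort.patient_ids, assignment)
    ]
    return results, _accuracy(results, labels), linkage


# ---------------------------------------------------------------------------
# nearest centroid / kNN


def centroid_classify(
    reference: CohortTable, query: pd.DataFrame, genes: list[str] | None = None
) -> list[ClassificationResult]:
    """Assign each query row to the class with the nearer mean z-scored profile.

    z-scoring statistics come from the reference cohort; exact distance ties
    go to sensitive.
    """
    genes = list(genes) if genes is not None else reference.genes
    missing = [g for g in genes if g not in query.columns]
    if missing:
        raise ValueError(f"query missing gene columns {missing}")
    ref_expr = reference.table[genes]
    mean = ref_expr.to_numpy(dtype=float).mean(axis=0)
    sd = ref_expr.to_numpy(dtype=float).std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(f"constant expression for genes {bad}")
    zref = _zscore(ref_expr, mean, sd)
    labels = reference.labels.to_numpy()
    centroids = {
        cls: zref[labels == cls].mean(axis=0) for cls in ("sensitive", "resistant")
    }
    zq = _zscore(query[genes], mean, sd)
    results = []
    for pid, row in zip(query.index, zq):
        d_sen = float(np.linalg.norm(row - centroids["sensitive"]))
        d_res = float(np.linalg.norm(row - centroids["resistant"]))
        predicted = "resistant" if d_res < d_sen else "sensitive"
        results.append(ClassificationResult(str(pid), predicted, None, "centroid"))
    return results


def knn_classify(
    reference: CohortTable, query: pd.DataFrame, k: int = 3, genes: list[str] | None = None
) -> list[ClassificationResult]:
    """Literal k-nearest-neighbour vote over reference patients (comparison mode)."""
    genes = list(genes) if genes is not None else reference.genes
    ref_expr = reference.table[genes]
    mean = ref_expr.to_numpy(dtype=float).mean(axis=0)
    sd = ref_expr.to_numpy(dtype=float).std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    zref = _zscore(ref_expr, mean, sd)
    labels = reference.labels.to_numpy()
    zq = _zscore(query[genes], mean, sd)
    results = []
    for pid, row in zip(query.index, zq):
        d = np.linalg.norm(zref - row, axis=1)
        nearest = labels[np.argsort(d, kind="stable")[:k]]
        n_res = int((nearest == "resistant").sum())
        predicted = "resistant" if n_res > k / 2 else "sensitive"
        results.append(ClassificationResult(str(pid), predicted, None, f"knn{k}"))
    return results
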