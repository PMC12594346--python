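"""Conditional linear Gaussian Bayesian-network classifier.

The top-k interactions of the hierarchy define a network over a binary
class node and the continuous expression nodes: the class is a parent
of every expression node, and each included interaction adds a
miRNA -> mRNA edge. miRNA nodes therefore follow a class-conditional
Gaussian N(mu(c), sigma^2(c)); each mRNA node follows a linear-Gaussian
N(beta0(c) + beta(c)^T y, sigma^2(c)) in its miRNA parents y. All
parameters are maximum-likelihood estimates on the training data
(variances divide by the per-class count; a small floor keeps them
positive). Classification picks the class maximising

    P(c) * prod_i P(x_i | parents_i, c)

computed in log space; the posterior is the two-class softmax of the
log-joints. A tie at posterior 0.5 resolves to class 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .engines_io import CandidatePool, ExpressionDataset
from .functional import CmiConfig, functional_scores
from .hierarchy import InteractionRanking, build_hierarchy

VARIANCE_FLOOR = 1e-8
_LOG_2PI = float(np.log(2 * np.pi))


@dataclass
class NetworkTopology:
    """DAG over the class node and the expression nodes for a given k."""

    mirnas: list[str]
    mrnas: list[str]
    parents: dict[str, list[str]]  # mRNA -> ordered miRNA parents
    interactions: list[tuple[str, str]]
    k: int

    @property
    def nodes(self) -> list[str]:
        return self.mirnas + self.mrnas

    def edges(self) -> list[tuple[str, str]]:
        """miRNA -> mRNA edges (the class->node edges are implicit)."""
        return [(m, g) for g in self.mrnas for m in self.parents[g]]


@dataclass
class CLGParameters:
    """Per-class parameters of the fitted network."""

    class_prior: dict[int, float]
    mirna_params: dict[str, dict[int, tuple[float, float]]]  # node -> c -> (mu, var)
    mrna_params: dict[str, dict[int, tuple[float, np.ndarray, float]]]  # node -> c -> (b0, beta, var)
    classes: tuple[int, int] = (0, 1)


@dataclass
class CVResult:
    """Per-k cross-validation metrics for the network-size sweep."""

    ks: np.ndarray
    accuracy_mean: np.ndarray
    accuracy_sd: np.ndarray
    auc_mean: np.ndarray
    auc_sd: np.ndarray
    best_k: int
    folds: int
    repeats: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "accuracy_mean": self.accuracy_mean,
                "accuracy_sd": self.accuracy_sd,
                "auc_mean": self.auc_mean,
                "auc_sd": self.auc_sd,
            }
        )


def build_topology(ranking: InteractionRanking, k: int) -> NetworkTopology:
    """Network structure induced by the first k ranked interactions."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range [1, {len(ranking)}]")
    chosen = ranking.top(k)
    mirnas: list[str] = []
    mrnas: list[str] = []
    parents: dict[str, list[str]] = {}
    for mirna, gene in chosen:
        if mirna not in mirnas:
            mirnas.append(mirna)
        if gene not in mrnas:
            mrnas.append(gene)
            parents[gene] = []
        parents[gene].append(mirna)
    return NetworkTopology(mirnas=mirnas, mrnas=mrnas, parents=parents,
                           interactions=chosen, k=k)


def fit_parameters(topology: NetworkTopology, data: ExpressionDataset) -> CLGParameters:
    """Maximum-likelihood CLG parameters from training data.

    miRNA nodes get per-class sample mean and MLE variance; mRNA nodes
    get per-class ordinary least squares on their miRNA parents with
    MLE residual variance. Variances are floored at 1e-8.
    """
    y = data.class_vector
    classes = tuple(int(v) for v in sorted(np.unique(y)))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    max_parents = max((len(p) for p in topology.parents.values()), default=0)
    prior: dict[int, float] = {}
    for c in classes:
        n_c = int((y == c).sum())
        if n_c < max_parents + 2:
            raise ValueError(
                f"class {c} has {n_c} samples, fewer than max parents + 2 "
                f"({max_parents + 2})"
            )
        prior[c] = n_c / len(y)

    missing = [n for n in topology.nodes if n not in data.matrix.columns]
    if missing:
        raise KeyError(f"expression data lacks network nodes: {missing}")

    mirna_params: dict[str, dict[int, tuple[float, float]]] = {}
    for node in topology.mirnas:
        v = data.matrix[node].to_numpy(float)
        mirna_params[node] = {}
        for c in classes:
            vc = v[y == c]
            mu = float(vc.mean())
            var = max(float(vc.var()), VARIANCE_FLOOR)  # MLE: divide by n_c
            mirna_params[node][c] = (mu, var)

    mrna_params: dict[str, dict[int, tuple[float, np.ndarray, float]]] = {}
    for node in topology.mrnas:
        target = data.matrix[node].to_numpy(float)
        design = data.matrix[topology.parents[node]].to_numpy(float)
        mrna_params[node] = {}
        for c in classes:
            sel = y == c
            X = np.column_stack([np.ones(sel.sum()), design[sel]])
            t = target[sel]
            coef, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
            if rank < X.shape[1]:
                raise np.linalg.LinAlgError(
                    f"singular design for node {node!r} in class {c}"
                )
            resid = t - X @ coef
            var = max(float(resid @ resid / len(t)), VARIANCE_FLOOR)
            mrna_params[node][c] = (float(coef[0]), coef[1:].copy(), var)
    return CLGParameters(class_prior=prior, mirna_params=mirna_params,
                         mrna_params=mrna_params, classes=classes)


def _gauss_logpdf(x: np.ndarray, mu: np.ndarray | float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mu) ** 2 / var)


def log_joint(
    params: CLGParameters,
    topology: NetworkTopology,
    samples: pd.DataFrame,
    c: int,
) -> np.ndarray:
    """log P(c) + sum of node log-densities under class c, per sample."""
    missing = [n for n in topology.nodes if n not in samples.columns]
    if missing:
        raise KeyError(f"samples lack network node columns: {missing}")
    out = np.full(len(samples), np.log(params.class_prior[c]))
    for node in topology.mirnas:
        mu, var = params.mirna_params[node][c]
        out += _gauss_logpdf(samples[node].to_numpy(float), mu, var)
    for node in topology.mrnas:
        b0, beta, var = params.mrna_params[node][c]
        mean = b0 + samples[topology.parents[node]].to_numpy(float) @ beta
        out += _gauss_logpdf(samples[node].to_numpy(float), mean, var)
    return out


def predict_proba(
    params: CLGParameters,
    topology: NetworkTopology,
    samples: pd.DataFrame,
) -> np.ndarray:
    """Two-column class posterior per sample (softmax of the log-joints)."""
    lj = np.column_stack([
        log_joint(params, topology, samples, c) for c in params.classes
    ])
    lj -= lj.max(axis=1, keepdims=True)
    p = np.exp(lj)
    return p / p.sum(axis=1, keepdims=True)


def predict(params: CLGParameters, topology: NetworkTopology,
            samples: pd.DataFrame) -> np.ndarray:
    """Argmax class; a tie at posterior 0.5 resolves to the first class."""
    proba = predict_proba(params, topology, samples)
    return np.where(proba[:, 1] > proba[:, 0], params.classes[1], params.classes[0])


def sweep_k(
    data: ExpressionDataset,
    pool: CandidatePool,
    si: np.ndarray,
    k_max: int,
    folds: int = 3,
    repeats: int = 3,
    seed: int = 0,
    cmi_cfg: CmiConfig | None = None,
    mode: str = "alternative",
    weight: float = 0.5,
    ties: str = "isolated",
) -> CVResult:
    """Cross-validated metrics for network sizes k = 1..k_max.

    Within each training fold the functional scores — and hence the
    hierarchy — are recomputed from the fold's training samples only,
    so no test information leaks into the ranking. Structural scores
    depend only on the databases and are split-invariant. Each repeat
    reshuffles the stratified folds with a seed derived from ``seed``.
    """
    y = data.class_vector
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("smallest class has fewer samples than folds")
    cmi_cfg = cmi_cfg or CmiConfig()
    acc = np.zeros((k_max, folds * repeats))
    auc = np.zeros((k_max, folds * repeats))
    col = 0
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed + 104729 * rep) % (2**31 - 1))
        for train_idx, test_idx in skf.split(data.matrix, y):
            train = ExpressionDataset(
                matrix=data.matrix.iloc[train_idx],
                feature_roles=data.feature_roles,
                class_vector=y[train_idx],
            )
            fi = functional_scores(train, pool, si, cmi_cfg)
            ranking = build_hierarchy(pool, si, fi, mode=mode, weight=weight, ties=ties)
            kk = min(k_max, len(ranking))
            test_X = data.matrix.iloc[test_idx]
            test_y = y[test_idx]
            for k in range(1, k_max + 1):
                topo = build_topology(ranking, min(k, kk))
                params = fit_parameters(topo, train)
                proba = predict_proba(params, topo, test_X)
                pred = np.where(proba[:, 1] > proba[:, 0],
                                params.classes[1], params.classes[0])
                acc[k - 1, col] = accuracy_score(test_y, pred)
                auc[k - 1, col] = roc_auc_score(test_y, proba[:, 1])
            col += 1
    ks = np.arange(1, k_max + 1)
    acc_mean = acc.mean(axis=1)
    best_k = int(ks[int(np.argmax(acc_mean))])
    return CVResult(
        ks=ks,
        accuracy_mean=acc_mean,
        accuracy_sd=acc.std(axis=1, ddof=1),
        auc_mean=auc.mean(axis=1),
        auc_sd=auc.std(axis=1, ddof=1),
        best_k=best_k,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization

def model_to_dict(topology: NetworkTopology, params: CLGParameters) -> dict:
    return {
        "topology": {
            "mirnas": topology.mirnas,
            "mrnas": topology.mrnas,
            "parents": topology.parents,
            "interactions": [list(p) for p in topology.interactions],
            "k": topology.k,
        },
        "parameters": {
            "class_prior": {str(c): p for c, p in params.class_prior.items()},
            "classes": list(params.classes),
            "mirna": {
                node: {str(c): list(v) for c, v in per.items()}
                for node, per in params.mirna_params.items()
            },
            "mrna": {
                node: {
                    str(c): [b0, list(map(float, beta)), var]
                    for c, (b0, beta, var) in per.items()
                }
                for node, per in params.mrna_params.items()
            },
        },
    }


def model_from_dict(doc: dict) -> tuple[NetworkTopology, CLGParameters]:
    t = doc["topology"]
    topology = NetworkTopology(
        mirnas=list(t["mirnas"]),
        mrnas=list(t["mrnas"]),
        parents={k: list(v) for k, v in t["parents"].items()},
        interactions=[tuple(p) for p in t["interactions"]],
        k=int(t["k"]),
    )
    p = doc["parameters"]
    params = CLGParameters(
        class_prior={int(c): float(v) for c, v in p["class_prior"].items()},
        classes=tuple(int(c) for c in p["classes"]),
        mirna_params={
            node: {int(c): (v[0], v[1]) for c, v in per.items()}
            for node, per in p["mirna"].items()
        },
        mrna_params={
            node: {
                int(c): (v[0], np.asarray(v[1], float), v[2])
                for c, v in per.items()
            }
            for node, per in p["mrna"].items()
        },
    )
    return topology, params


def save_model(path: str | Path, topology: NetworkTopology, params: CLGParameters) -> None:
    Path(path).write_text(json.dumps(model_to_dict(topology, params), indent=1))


def load_model(path: str | Path) -> tuple[NetworkTopology, CLGParameters]:
    return model_from_dict(json.loads(Path(path).read_text()))
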