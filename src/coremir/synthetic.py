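"""Synthetic data with known ground truth, plus preprocessing helpers.

The generator emulates the real inputs at toy scale: four engine
tables in which planted "true" interactions appear with high
probability and decoys with low probability, a GENCODE-style gene
annotation, and paired expression sampled from the same conditional
linear Gaussian family the classifier assumes (miRNAs Gaussian per
class, mRNAs linear-Gaussian in their true miRNA regulators per
class). Because the generative model matches the classifier family,
recovery tests measure the pipeline, not model mismatch; see the
methods note for what this does and does not establish about real
RNA-seq data.

The module also carries the dataset-preparation helpers used on real
count data: role-aware low-count filters, log2(x+1) normalisation and
survival-based binary class assignment with the censoring-eligibility
rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engines_io import (
    ENGINE_NAMES,
    EngineTable,
    ExpressionDataset,
    GeneAnnotation,
)


@dataclass
class InteractionParams:
    """Per-class generative parameters of one true interaction."""

    mirna: str
    gene: str
    mu: dict[int, float]  # class -> miRNA mean
    sigma2: dict[int, float]  # class -> miRNA variance
    beta0: dict[int, float]  # class -> mRNA intercept
    beta: dict[int, float]  # class -> regression slope on the miRNA
    noise2: dict[int, float]  # class -> mRNA residual variance


@dataclass
class GenerativeSpec:
    """Ground-truth description of a synthetic study.

    ``p_true`` / ``p_decoy`` are per-engine membership probabilities
    for planted interactions and decoy pairs respectively. Decoy pairs
    are sampled from the remaining miRNA x mRNA grid.
    """

    n_mirna: int
    n_mrna: int
    n_per_class: int
    true_interactions: list[InteractionParams]
    p_true: float = 0.9
    p_decoy: float = 0.3
    n_decoy: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        grid = {(m, g) for m in self.mirna_ids for g in self.gene_symbols}
        for t in self.true_interactions:
            if (t.mirna, t.gene) not in grid:
                raise ValueError(f"true interaction {(t.mirna, t.gene)} outside the grid")
            if any(v <= 0 for v in t.sigma2.values()) or any(v <= 0 for v in t.noise2.values()):
                raise ValueError("variances must be positive")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"hsa-miR-{i + 1:03d}" for i in range(self.n_mirna)]

    @property
    def gene_symbols(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_mrna)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"ENSG{i + 1:011d}" for i in range(self.n_mrna)]

    @property
    def true_pairs(self) -> list[tuple[str, str]]:
        return [(t.mirna, t.gene) for t in self.true_interactions]


def make_spec(
    n_mirna: int = 10,
    n_mrna: int = 20,
    n_true: int = 5,
    n_per_class: int = 300,
    n_decoy: int = 60,
    effect: float = 1.5,
    p_true: float = 0.9,
    p_decoy: float = 0.3,
    seed: int = 0,
) -> GenerativeSpec:
    """Random ground-truth spec with class-informative true interactions.

    Each true interaction separates the classes through both a miRNA
    mean shift and a class-dependent regulation slope, both scaled by
    ``effect`` (0 gives a null model whose expression is independent of
    the class). Defaults emulate a small but realistic study: tens of
    candidate molecules, a handful of real signals buried among decoys,
    a few hundred samples.
    """
    rng = np.random.default_rng(seed)
    mirnas = [f"hsa-miR-{i + 1:03d}" for i in range(n_mirna)]
    genes = [f"GENE{i + 1:04d}" for i in range(n_mrna)]
    chosen_m = rng.choice(n_mirna, size=min(n_true, n_mirna), replace=False)
    chosen_g = rng.choice(n_mrna, size=min(n_true, n_mrna), replace=False)
    true: list[InteractionParams] = []
    for im, ig in zip(chosen_m, chosen_g):
        base_mu = rng.normal(5.0, 1.0)
        shift = effect * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
        slope0 = rng.uniform(-1.5, 1.5)
        slope_shift = effect * rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.8)
        true.append(
            InteractionParams(
                mirna=mirnas[im],
                gene=genes[ig],
                mu={0: base_mu, 1: base_mu + shift},
                sigma2={0: 1.0, 1: 1.0},
                beta0={0: rng.normal(8.0, 1.0), 1: rng.normal(8.0, 1.0) if effect > 0 else 0.0},
                beta={0: slope0, 1: slope0 + slope_shift},
                noise2={0: 1.0, 1: 1.0},
            )
        )
    if effect == 0:
        # strict null: identical parameters across classes
        for t in true:
            t.mu[1] = t.mu[0]
            t.beta0[1] = t.beta0[0]
            t.beta[1] = t.beta[0]
    return GenerativeSpec(
        n_mirna=n_mirna,
        n_mrna=n_mrna,
        n_per_class=n_per_class,
        true_interactions=true,
        p_true=p_true,
        p_decoy=p_decoy,
        n_decoy=n_decoy,
        seed=seed,
    )


def make_panel(spec: GenerativeSpec) -> tuple[list[EngineTable], GeneAnnotation]:
    """Four engine tables plus gene annotation for a synthetic study.

    True interactions enter each engine independently with probability
    ``p_true`` (every true pair is guaranteed into at least one engine
    so it is never lost from the candidate pool); decoys enter with
    probability ``p_decoy``. The annotation covers every gene.
    """
    rng = np.random.default_rng(spec.seed + 1)
    true_pairs = spec.true_pairs
    grid = [
        (m, g)
        for m in spec.mirna_ids
        for g in spec.gene_symbols
        if (m, g) not in set(true_pairs)
    ]
    n_decoy = min(spec.n_decoy, len(grid))
    decoy_idx = rng.choice(len(grid), size=n_decoy, replace=False)
    decoys = [grid[i] for i in sorted(decoy_idx)]

    membership: dict[tuple[str, str], np.ndarray] = {}
    for pair in true_pairs:
        row = rng.random(4) < spec.p_true
        if not row.any() and spec.p_true > 0:
            row[rng.integers(4)] = True
        membership[pair] = row
    for pair in decoys:
        membership[pair] = rng.random(4) < spec.p_decoy

    symbol_of = dict(zip(spec.gene_symbols, spec.gene_ids))
    tables = []
    for k, name in enumerate(ENGINE_NAMES):
        pairs = set()
        for (m, g), row in membership.items():
            if row[k]:
                # engines speak Ensembl ids; normalisation maps them back
                pairs.add((m, symbol_of[g]))
        tables.append((name, pairs))
    annotation = GeneAnnotation(
        id_to_symbol=dict(zip(spec.gene_ids, spec.gene_symbols))
    )
    engine_tables = [
        EngineTable(
            name=name,
            interactions=frozenset(
                (m, annotation.symbol(g)) for m, g in pairs
            ),
        )
        for name, pairs in tables
    ]
    return engine_tables, annotation


def sample_expression(spec: GenerativeSpec) -> ExpressionDataset:
    """Draw a balanced expression dataset from the ground-truth CLG.

    Regulator miRNAs are sampled from their per-class Gaussians, their
    target mRNAs from the linear-Gaussian response; background
    molecules (not in any true interaction) are class-independent
    noise around typical log-expression levels. Ancestral order is
    respected (miRNAs before mRNAs).
    """
    rng = np.random.default_rng(spec.seed + 2)
    n = spec.n_per_class
    classes = np.repeat([0, 1], n)
    n_total = 2 * n
    cols: dict[str, np.ndarray] = {}
    # background levels, class-independent
    for m in spec.mirna_ids:
        cols[m] = rng.normal(5.0, 1.0, n_total)
    for g in spec.gene_symbols:
        cols[g] = rng.normal(8.0, 1.0, n_total)
    # overwrite regulators, then targets (ancestral order)
    for t in spec.true_interactions:
        v = np.empty(n_total)
        for c in (0, 1):
            sel = classes == c
            v[sel] = rng.normal(t.mu[c], np.sqrt(t.sigma2[c]), sel.sum())
        cols[t.mirna] = v
    for t in spec.true_interactions:
        v = np.empty(n_total)
        for c in (0, 1):
            sel = classes == c
            v[sel] = (
                t.beta0[c]
                + t.beta[c] * cols[t.mirna][sel]
                + rng.normal(0, np.sqrt(t.noise2[c]), sel.sum())
            )
        cols[t.gene] = v
    matrix = pd.DataFrame(
        cols,
        index=[f"S{i + 1:04d}" for i in range(n_total)],
        columns=spec.mirna_ids + spec.gene_symbols,
    )
    roles = pd.Series(
        ["mirna"] * spec.n_mirna + ["mrna"] * spec.n_mrna,
        index=matrix.columns,
    )
    return ExpressionDataset(matrix=matrix, feature_roles=roles, class_vector=classes)


def write_fixture_bundle(spec: GenerativeSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write engines, annotation, expression and classes as flat files.

    Produces the same dialects the readers consume: two-column TSV
    engine tables (Ensembl gene ids), a GENCODE-style GTF, an
    expression CSV (samples x features) and a class CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tables, annotation = make_panel(spec)
    symbol_to_id = {v: k for k, v in annotation.id_to_symbol.items()}
    for table in tables:
        p = out / f"{table.name}.tsv"
        rows = sorted((m, symbol_to_id.get(g, g)) for m, g in table.interactions)
        with open(p, "w") as fh:
            fh.write("mirna\tgene\n")
            for m, g in rows:
                fh.write(f"{m}\t{g}.1\n")  # version suffix exercises stripping
        paths[table.name] = p
    gtf = out / "annotation.gtf"
    with open(gtf, "w") as fh:
        fh.write("##description: synthetic toy annotation\n")
        for i, (gid, sym) in enumerate(sorted(annotation.id_to_symbol.items())):
            start = 1000 * (i + 1)
            fh.write(
                f"chr1\tSYNTH\tgene\t{start}\t{start + 500}\t.\t+\t.\t"
                f'gene_id "{gid}.1"; gene_name "{sym}"; gene_type "protein_coding";\n'
            )
    paths["annotation"] = gtf
    data = sample_expression(spec)
    expr = out / "expression.csv"
    data.matrix.round(6).to_csv(expr, index_label="sample_id")
    paths["expression"] = expr
    cls = out / "classes.csv"
    pd.DataFrame(
        {"sample_id": data.sample_ids, "class": data.class_vector}
    ).to_csv(cls, index=False)
    paths["classes"] = cls
    return paths


# ---------------------------------------------------------------------------
# preprocessing helpers for real count data


@dataclass
class SurvivalTable:
    """Per-sample follow-up times (days) and censoring status."""

    sample_ids: list[str]
    times: np.ndarray
    censored: np.ndarray  # bool: True = censored (alive at last follow-up)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.censored = np.asarray(self.censored, bool)
        if (self.times < 0).any():
            raise ValueError("survival/follow-up times must be >= 0")
        if not (len(self.sample_ids) == len(self.times) == len(self.censored)):
            raise ValueError("sample_ids, times and censored must align")


@dataclass
class SurvivalClasses:
    classes: pd.Series  # sample id -> 0 (short survival) / 1 (long survival)
    excluded: list[str]
    balanced: bool


def assign_survival_classes(table: SurvivalTable) -> SurvivalClasses:
    """Binary survival classes with the censoring-eligibility rule.

    The 75% of uncensored samples with the shortest survival (rounded
    down) form the short-survival class (0). The remaining uncensored
    samples seed the long-survival class (1), which is topped up with
    the longest-follow-up censored samples until the classes balance.
    A censored sample is eligible only if its follow-up time exceeds
    the maximum survival observed in the short class. Everything not
    assigned is excluded. Ties in time break by sample id.
    """
    unc = [(t, s) for s, t, c in zip(table.sample_ids, table.times, table.censored) if not c]
    if len(unc) < 4:
        raise ValueError("need at least 4 uncensored samples")
    unc.sort()
    n_short = int(np.floor(0.75 * len(unc)))
    short = unc[:n_short]
    long_unc = unc[n_short:]
    max_short = max(t for t, _ in short)
    cens = sorted(
        ((t, s) for s, t, c in zip(table.sample_ids, table.times, table.censored) if c),
        reverse=True,
    )
    eligible = [(t, s) for t, s in cens if t > max_short]
    need = len(short) - len(long_unc)
    chosen_cens = eligible[:max(need, 0)]
    balanced = len(long_unc) + len(chosen_cens) == len(short)
    if not balanced:
        warnings.warn(
            f"cannot balance classes: short={len(short)}, "
            f"long={len(long_unc) + len(chosen_cens)} "
            f"(eligible censored pool exhausted)",
            stacklevel=2,
        )
    assigned = {s: 0 for _, s in short}
    assigned.update({s: 1 for _, s in long_unc})
    assigned.update({s: 1 for _, s in chosen_cens})
    excluded = [s for s in table.sample_ids if s not in assigned]
    classes = pd.Series({s: assigned[s] for s in table.sample_ids if s in assigned},
                        dtype=int)
    return SurvivalClasses(classes=classes, excluded=excluded, balanced=balanced)


def filter_low_counts(
    counts: pd.DataFrame,
    roles: pd.Series,
    mrna_min_count: int = 5,
    mirna_min_count: int = 1,
    max_low_fraction: float = 0.25,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop weakly expressed features from a raw count matrix.

    An mRNA is dropped when more than 25% of samples show fewer than 5
    counts; a miRNA when more than 25% show fewer than 1 count. The
    "more than" is strict: a feature sitting exactly at the threshold
    fraction is kept. Returns the filtered matrix and the dropped
    feature names.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be nonnegative")
    dropped: list[str] = []
    for feat in counts.columns:
        threshold = mirna_min_count if roles[feat] == "mirna" else mrna_min_count
        low_frac = (counts[feat] < threshold).mean()
        if low_frac > max_low_fraction:
            dropped.append(feat)
    return counts.drop(columns=dropped), dropped


def log_normalize(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise log2(x + 1) on nonnegative counts."""
    arr = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("log_normalize requires nonnegative input")
    if isinstance(counts, pd.DataFrame):
        return np.log2(counts + 1)
    return np.log2(arr + 1.0)
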