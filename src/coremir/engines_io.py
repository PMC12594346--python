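"""Reading and harmonising miRNA-target interaction sources.

Candidate miRNA-mRNA interactions come from four "engines": two
prediction databases (TargetScan-style and DIANA-microT-style) and two
experimental-validation databases (miRTarBase-style and TarBase-style).
The engines disagree on gene identifier conventions, so everything is
mapped to gene symbols through a GENCODE-style annotation before any
set operation. Only pairs supported by at least one engine, and whose
endpoints are both measured in the expression dataset, survive into the
candidate pool.
"""

from __future__ import annotations

import hashlib
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical engine order used for presence masks throughout the package.
ENGINE_NAMES = ("targetscan", "diana", "mirtarbase", "tarbase")

ENGINE_KINDS = {
    "targetscan": "predicted",
    "diana": "predicted",
    "mirtarbase": "validated",
    "tarbase": "validated",
}

_ENSEMBL_VERSION = re.compile(r"^(ENS[A-Z]*[GTEP]\d+)\.\d+$")


class EngineFormatError(ValueError):
    """A delimited engine table is missing a mapped column."""


class EmptyPoolError(ValueError):
    """No candidate interaction survived filtering."""


@dataclass(frozen=True)
class EngineTable:
    """One miRNA-target interaction source.

    Parameters
    ----------
    name:
        One of ``targetscan``, ``diana``, ``mirtarbase``, ``tarbase``.
    interactions:
        Deduplicated set of ``(mirna_id, gene_symbol)`` pairs after
        identifier normalisation.
    """

    name: str
    interactions: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.name not in ENGINE_NAMES:
            raise ValueError(f"unknown engine name {self.name!r}; expected one of {ENGINE_NAMES}")

    @property
    def kind(self) -> str:
        """``predicted`` or ``validated``."""
        return ENGINE_KINDS[self.name]

    def __len__(self) -> int:
        return len(self.interactions)


@dataclass
class GeneAnnotation:
    """Bidirectional gene_id <-> gene_symbol mapping.

    Many-to-one symbol collisions are allowed; the colliding symbols are
    recorded in :attr:`collisions`. Lookups of unknown identifiers return
    the input unchanged and are counted in :attr:`unmapped`.
    """

    id_to_symbol: dict[str, str]
    collisions: set[str] = field(default_factory=set)
    unmapped: dict[str, int] = field(default_factory=dict)

    def symbol(self, gene_id: str) -> str:
        base = strip_ensembl_version(gene_id)
        try:
            return self.id_to_symbol[base]
        except KeyError:
            self.unmapped[base] = self.unmapped.get(base, 0) + 1
            return base

    @property
    def n_unmapped(self) -> int:
        return sum(self.unmapped.values())


@dataclass
class ExpressionDataset:
    """Paired miRNA/mRNA expression with a binary phenotype.

    ``matrix`` is samples x features, log-scale, no missing values.
    ``feature_roles`` partitions the columns into ``mirna`` and ``mrna``.
    """

    matrix: pd.DataFrame
    feature_roles: pd.Series  # index = feature ids, values in {"mirna", "mrna"}
    class_vector: np.ndarray  # shape (n_samples,), values in {0, 1}

    def __post_init__(self) -> None:
        self.class_vector = np.asarray(self.class_vector)
        if len(self.class_vector) != self.matrix.shape[0]:
            raise ValueError(
                f"class vector length {len(self.class_vector)} != "
                f"number of samples {self.matrix.shape[0]}"
            )
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not set(self.feature_roles.unique()) <= {"mirna", "mrna"}:
            raise ValueError("feature roles must be 'mirna' or 'mrna'")
        if list(self.feature_roles.index) != list(self.matrix.columns):
            raise ValueError("feature_roles index must match matrix columns")

    @property
    def sample_ids(self) -> Sequence[str]:
        return list(self.matrix.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.feature_roles[self.feature_roles == "mirna"].index)

    @property
    def mrnas(self) -> list[str]:
        return list(self.feature_roles[self.feature_roles == "mrna"].index)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.matrix.to_numpy(float)).tobytes())
        h.update(",".join(map(str, self.matrix.columns)).encode())
        h.update(self.class_vector.astype(np.int64).tobytes())
        return h.hexdigest()[:16]


@dataclass
class CandidatePool:
    """Filtered set S of biologically plausible miRNA-mRNA pairs.

    ``interactions`` is deterministically ordered (lexicographic by
    (mirna, gene)); ``presence`` holds one boolean row per interaction in
    the canonical engine order; ``occurrence_counts`` counts, per
    molecule, how many pool interactions it participates in.
    """

    interactions: list[tuple[str, str]]
    presence: np.ndarray  # shape (n_interactions, 4), bool
    occurrence_counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.interactions)

    def presence_mask(self, i: int) -> str:
        """4-character 0/1 string in canonical engine order."""
        return "".join("1" if b else "0" for b in self.presence[i])

    def isolation(self, i: int) -> int:
        """Sum of endpoint occurrence counts (low = isolated)."""
        m, g = self.interactions[i]
        return self.occurrence_counts[m] + self.occurrence_counts[g]


def strip_ensembl_version(identifier: str) -> str:
    """Drop a trailing ``.NN`` version from an Ensembl-style id."""
    m = _ENSEMBL_VERSION.match(identifier)
    return m.group(1) if m else identifier


def normalize_identifier(raw: str, role: str, annotation: GeneAnnotation | None = None) -> str:
    """Normalise a molecule identifier.

    miRNA ids are whitespace-stripped and returned otherwise unchanged
    (matching elsewhere is case-insensitive). Gene ids lose any Ensembl
    version suffix and are mapped to symbols when the annotation knows
    them; unknown ids pass through unchanged and are counted on the
    annotation object.
    """
    ident = raw.strip()
    if role == "mirna":
        return ident
    ident = strip_ensembl_version(ident)
    if annotation is not None:
        ident = annotation.symbol(ident)
    return ident


def read_gtf_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene_id/gene_name pairs from the ``gene`` lines of a GTF.

    Only the GENCODE dialect attributes ``gene_id`` and ``gene_name``
    are consumed; all other feature types and attributes are ignored.
    """
    id_re = re.compile(r'gene_id "([^"]+)"')
    name_re = re.compile(r'gene_name "([^"]+)"')
    mapping: dict[str, str] = {}
    seen_symbols: dict[str, str] = {}
    collisions: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = fields[8]
            m_id, m_name = id_re.search(attrs), name_re.search(attrs)
            if not (m_id and m_name):
                continue
            gid = strip_ensembl_version(m_id.group(1))
            sym = m_name.group(1)
            mapping[gid] = sym
            if sym in seen_symbols and seen_symbols[sym] != gid:
                collisions.add(sym)
            seen_symbols[sym] = gid
    if collisions:
        logger.warning("annotation: %d symbols map from multiple gene ids", len(collisions))
    return GeneAnnotation(id_to_symbol=mapping, collisions=collisions)


def read_engine_table(
    path: str | Path,
    name: str,
    format_spec: Mapping[str, str] | None = None,
    annotation: GeneAnnotation | None = None,
    sep: str = "\t",
) -> EngineTable:
    """Read one delimited engine table.

    ``format_spec`` maps the logical columns ``mirna`` and ``gene`` to
    the file's column names; the bundled fixture dialect uses columns
    named exactly ``mirna`` and ``gene``.
    """
    spec = {"mirna": "mirna", "gene": "gene"}
    if format_spec:
        spec.update(format_spec)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for logical, column in spec.items():
        if column not in df.columns:
            raise EngineFormatError(
                f"engine table {path}: mapped {logical} column {column!r} not found "
                f"(columns: {list(df.columns)})"
            )
    n_raw = len(df)
    pairs = {
        (
            normalize_identifier(m, "mirna"),
            normalize_identifier(g, "gene", annotation),
        )
        for m, g in zip(df[spec["mirna"]], df[spec["gene"]])
        if isinstance(m, str) and isinstance(g, str) and m.strip() and g.strip()
    }
    n_dropped = n_raw - len(pairs)
    logger.info("engine %s: read %d rows, %d unique pairs (%d duplicates/blank dropped)",
                name, n_raw, len(pairs), n_dropped)
    if not pairs:
        warnings.warn(f"engine table {name} at {path} contains no interactions", stacklevel=2)
    return EngineTable(name=name, interactions=frozenset(pairs))


def check_engines(panel: Sequence[EngineTable]) -> dict:
    """Verify that a four-engine panel is usable.

    Returns a report with per-engine presence and counts, pairwise
    overlap counts, and an overall ``status`` that is ``"pass"`` iff all
    four engines are present and non-empty.
    """
    by_name = {t.name: t for t in panel}
    engines_report = {}
    failures = []
    for name in ENGINE_NAMES:
        table = by_name.get(name)
        count = len(table) if table is not None else 0
        engines_report[name] = {"present": table is not None, "interactions": count}
        if count == 0:
            failures.append(name)
    overlaps = {}
    for i, a in enumerate(ENGINE_NAMES):
        for b in ENGINE_NAMES[i + 1:]:
            ta, tb = by_name.get(a), by_name.get(b)
            overlaps[f"{a}|{b}"] = (
                len(ta.interactions & tb.interactions) if ta and tb else 0
            )
    return {
        "engines": engines_report,
        "overlaps": overlaps,
        "status": "pass" if not failures else "fail",
        "failed_engines": failures,
    }


def _infer_roles(columns: Iterable[str]) -> pd.Series:
    cols = list(columns)
    roles = ["mirna" if c.lower().startswith("hsa-") else "mrna" for c in cols]
    return pd.Series(roles, index=cols)


def read_expression(
    expression_path: str | Path,
    classes_path: str | Path,
    annotation: GeneAnnotation | None = None,
    roles: Mapping[str, str] | None = None,
) -> ExpressionDataset:
    """Load a samples-x-features expression CSV plus a class CSV.

    The expression file's first column is the sample id; the class file
    has columns (sample id, class) with class in {0, 1}. Gene columns
    are mapped to symbols through the annotation. Feature roles come
    from ``roles`` when given, else from the ``hsa-`` prefix rule.
    """
    matrix = pd.read_csv(expression_path, index_col=0)
    classes = pd.read_csv(classes_path, index_col=0).iloc[:, 0]
    classes = classes.reindex(matrix.index)
    if classes.isna().any():
        missing = list(matrix.index[classes.isna()])[:5]
        raise ValueError(f"class file missing samples, e.g. {missing}")
    if roles is not None:
        role_series = pd.Series({c: roles[c] for c in matrix.columns})
    else:
        role_series = _infer_roles(matrix.columns)
    if annotation is not None:
        renames = {
            c: normalize_identifier(c, "gene", annotation)
            for c in matrix.columns
            if role_series[c] == "mrna"
        }
        matrix = matrix.rename(columns=renames)
        role_series.index = matrix.columns
    return ExpressionDataset(
        matrix=matrix,
        feature_roles=role_series,
        class_vector=classes.to_numpy(int),
    )


def build_candidate_pool(data: ExpressionDataset, panel: Sequence[EngineTable]) -> CandidatePool:
    """Filter engine interactions down to the candidate pool S.

    A pair enters the pool iff both endpoints are features of ``data``
    and the pair appears in at least one engine. miRNA matching is
    case-insensitive; the dataset's spelling is canonical.
    """
    mirna_lookup = {m.casefold(): m for m in data.mirnas}
    gene_set = set(data.mrnas)
    by_name = {t.name: t for t in panel}
    tables = [by_name.get(name, EngineTable(name, frozenset())) for name in ENGINE_NAMES]

    candidate: dict[tuple[str, str], np.ndarray] = {}
    for k, table in enumerate(tables):
        for mirna, gene in table.interactions:
            canon_m = mirna_lookup.get(mirna.casefold())
            if canon_m is None or gene not in gene_set:
                continue
            key = (canon_m, gene)
            if key not in candidate:
                candidate[key] = np.zeros(4, dtype=bool)
            candidate[key][k] = True

    if not candidate:
        raise EmptyPoolError(
            "no candidate interactions: no engine pair matched the dataset's features; "
            "check that miRNA names and gene symbols share a namespace with the engines"
        )
    interactions = sorted(candidate)
    presence = np.array([candidate[key] for key in interactions], dtype=bool)
    occurrence: dict[str, int] = {}
    for mirna, gene in interactions:
        occurrence[mirna] = occurrence.get(mirna, 0) + 1
        occurrence[gene] = occurrence.get(gene, 0) + 1
    return CandidatePool(interactions=interactions, presence=presence, occurrence_counts=occurrence)


def download(config_path: str | Path, dest_dir: str | Path) -> None:  # pragma: no cover
    """Fetch engine tables and annotation from configured URLs.

    Stub interface: reads a two-column config (name, url[, sha256]) and
    downloads each resource into ``dest_dir``, verifying checksums when
    given. Network retrieval is intentionally not exercised by the test
    suite; point the readers at local files instead.
    """
    import json
    import urllib.request

    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    with open(config_path) as fh:
        entries = json.load(fh)
    for entry in entries:
        target = dest / entry["name"]
        urllib.request.urlretrieve(entry["url"], target)
        if "sha256" in entry:
            digest = hashlib.sha256(target.read_bytes()).hexdigest()
            if digest != entry["sha256"]:
                raise IOError(f"checksum mismatch for {entry['name']}")
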