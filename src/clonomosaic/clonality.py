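"""Clonotype construction and repertoire clonality statistics.

A clonotype groups cells sharing identical rearranged TCR features (V gene,
J gene, CDR3 nucleotide sequence per chain); counts are cells, not UMIs.
Diversity is summarized by the inverse Simpson index D = 1 / sum(p_c^2) —
the effective number of equally abundant clones — made comparable across
sequencing depths by equal-depth downsampling (multivariate hypergeometric
subsampling of the cell multiset) with bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import ClonotypeRecord

logger = logging.getLogger(__name__)

DEFAULT_OCCUPANCY_EDGES = (0.0, 1e-4, 1e-3, 1e-2, 0.1, 1.0)


class ClonotypeKey(NamedTuple):
    """Identity of a clonotype: (V, J, CDR3nt) per chain; None where absent."""

    v_tra: str | None
    j_tra: str | None
    cdr3_nt_tra: str | None
    v_trb: str | None
    j_trb: str | None
    cdr3_nt_trb: str | None


@dataclass(frozen=True)
class Clonotype:
    key: ClonotypeKey
    cells: frozenset[str]

    @property
    def n_c(self) -> int:
        return len(self.cells)


@dataclass
class Repertoire:
    """A sample's clonotypes with cell counts; the unit of diversity analysis."""

    sample_id: str
    clonotypes: list[Clonotype]
    scheme: str = "paired"
    n_excluded_cells: int = 0

    def __post_init__(self) -> None:
        if not self.clonotypes:
            raise ValueError("empty repertoire")
        keys = [c.key for c in self.clonotypes]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate clonotype keys in repertoire")

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.n_c for c in self.clonotypes], dtype=np.int64)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        counts = self.counts
        return counts / counts.sum()

    @classmethod
    def from_counts(cls, sample_id: str, counts: dict | Sequence[int], scheme: str = "paired"):
        """Build a repertoire from clone counts alone (synthetic keys/cells).

        Convenient for diversity computations where sequence identity is
        irrelevant; counts may be a mapping key->count or a plain sequence.
        """
        if not isinstance(counts, dict):
            counts = {f"clone{i:05d}": int(n) for i, n in enumerate(counts)}
        clones = []
        cell_no = 0
        for name, n in counts.items():
            if n < 1:
                raise ValueError(f"clone {name} has count {n} < 1")
            key = name if isinstance(name, ClonotypeKey) else ClonotypeKey(
                None, None, None, "TRBV0", "TRBJ0", str(name)
            )
            cells = frozenset(f"{sample_id}-cell{cell_no + j:07d}" for j in range(n))
            cell_no += n
            clones.append(Clonotype(key, cells))
        return cls(sample_id, clones, scheme=scheme)


@dataclass(frozen=True)
class DiversityEstimate:
    index_name: str
    depth: int
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class CloneClass:
    key: ClonotypeKey
    n_c: int
    proportion: float
    clone_class: str  # "singlet" | "expanded"
    dominant: bool


def _best_contig(contigs: list[ClonotypeRecord]) -> ClonotypeRecord:
    # highest UMI count wins; ties broken lexicographically by CDR3nt
    return min(contigs, key=lambda r: (-r.umi_count, r.cdr3_nt))


def build_repertoire(
    records: Sequence[ClonotypeRecord],
    sample_id: str = "sample",
    scheme: str = "paired",
    productive_only: bool = True,
) -> Repertoire:
    """Collapse per-cell contigs into clonotypes.

    scheme="paired": key is (V, J, CDR3nt) of both chains; a cell missing one
    chain falls back to the present chain's key.  scheme="beta": only the TRB
    chain identifies the clonotype; cells without a productive TRB are
    excluded.  Multi-chain cells keep the highest-UMI contig per chain.
    """
    if scheme not in ("paired", "beta"):
        raise ValueError(f"unknown clonotype scheme {scheme!r}")
    by_cell: dict[str, dict[str, list[ClonotypeRecord]]] = defaultdict(lambda: defaultdict(list))
    for rec in records:
        if productive_only and not rec.productive:
            continue
        by_cell[rec.cell_barcode][rec.chain].append(rec)

    cells_by_key: dict[ClonotypeKey, set[str]] = defaultdict(set)
    n_excluded = 0
    all_barcodes = {r.cell_barcode for r in records}
    for barcode in all_barcodes:
        chains = by_cell.get(barcode, {})
        tra = _best_contig(chains["TRA"]) if chains.get("TRA") else None
        trb = _best_contig(chains["TRB"]) if chains.get("TRB") else None
        if scheme == "beta":
            tra = None
        if tra is None and trb is None:
            n_excluded += 1
            continue
        key = ClonotypeKey(
            tra.v_gene if tra else None,
            tra.j_gene if tra else None,
            tra.cdr3_nt if tra else None,
            trb.v_gene if trb else None,
            trb.j_gene if trb else None,
            trb.cdr3_nt if trb else None,
        )
        cells_by_key[key].add(barcode)

    if not cells_by_key:
        raise ValueError("empty repertoire: every cell was excluded")
    if n_excluded:
        logger.info("%s: excluded %d cells with no usable chain", sample_id, n_excluded)
    # None-safe deterministic ordering of keys
    clonotypes = [
        Clonotype(k, frozenset(v))
        for k, v in sorted(
            cells_by_key.items(), key=lambda kv: tuple("" if f is None else f for f in kv[0])
        )
    ]
    return Repertoire(sample_id, clonotypes, scheme=scheme, n_excluded_cells=n_excluded)


# --- diversity indices ----------------------------------------------------


def inverse_simpson(rep: Repertoire | np.ndarray) -> float:
    """D = 1 / sum(p_c^2): effective number of equally abundant clones."""
    p = rep.proportions if isinstance(rep, Repertoire) else np.asarray(rep, float)
    p = p / p.sum()
    return float(1.0 / np.square(p).sum())


def shannon(rep: Repertoire | np.ndarray) -> float:
    p = rep.proportions if isinstance(rep, Repertoire) else np.asarray(rep, float)
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def richness(rep: Repertoire | np.ndarray) -> float:
    p = rep.proportions if isinstance(rep, Repertoire) else np.asarray(rep, float)
    return float(np.count_nonzero(p))


_INDEX_FUNCS = {"inverse_simpson": inverse_simpson, "shannon": shannon, "richness": richness}

_VECTOR_INDEX = {
    "inverse_simpson": lambda P: 1.0 / np.square(P).sum(axis=1),
    "shannon": lambda P: -np.sum(np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0), axis=1),
    "richness": lambda P: np.count_nonzero(P, axis=1).astype(float),
}


def downsampled_diversity(
    rep: Repertoire,
    depth: int,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
    index: str = "inverse_simpson",
    with_replacement: bool = False,
) -> DiversityEstimate:
    """Equal-depth downsampling bootstrap of a diversity index.

    Each bootstrap iteration draws ``depth`` cells without replacement from
    the repertoire's cell multiset (multivariate hypergeometric over clone
    counts) and recomputes the index; the point estimate is the resample
    mean and the CI the empirical quantiles.  ``with_replacement=True``
    switches to multinomial resampling at depth.
    """
    if index not in _VECTOR_INDEX:
        raise ValueError(f"unknown index {index!r}")
    if not 0 < ci < 1:
        raise ValueError("ci must be in (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    counts = rep.counts
    N = int(counts.sum())
    if depth > N:
        raise ValueError(
            f"depth {depth} exceeds repertoire size {N}; "
            "set the common depth to the minimum sample size across compared repertoires"
        )
    rng = np.random.default_rng(seed)
    if with_replacement:
        draws = rng.multinomial(depth, counts / N, size=n_boot)
    else:
        draws = rng.multivariate_hypergeometric(counts, depth, size=n_boot)
    values = _VECTOR_INDEX[index](draws / depth)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    point = float(values.mean())
    return DiversityEstimate(index, depth, point, float(min(lo, point)), float(max(hi, point)), n_boot, seed)


def common_depth(reps: Sequence[Repertoire]) -> int:
    """The only depth valid for every compared repertoire: the minimum N."""
    return min(r.N for r in reps)


def diversity_table(
    reps: Sequence[Repertoire],
    depth: int | None = None,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
    index: str = "inverse_simpson",
) -> pd.DataFrame:
    """Per-sample diversity estimates at a shared downsampling depth."""
    if depth is None:
        depth = common_depth(reps)
    rows = []
    for i, rep in enumerate(reps):
        est = downsampled_diversity(rep, depth, n_boot=n_boot, ci=ci, seed=seed + i, index=index)
        rows.append(
            {
                "sample": rep.sample_id,
                "index": est.index_name,
                "depth": est.depth,
                "point": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_boot": est.n_boot,
                "seed": est.seed,
            }
        )
    return pd.DataFrame(rows)


# --- occupancy & classification -------------------------------------------


def occupancy_profile(
    rep: Repertoire, edges: Sequence[float] = DEFAULT_OCCUPANCY_EDGES
) -> dict[tuple[float, float], float]:
    """Proportional repertoire occupancy across clone-size bins.

    Bins are right-closed intervals (lo, hi] over clone proportions, must be
    ordered and cover (0, 1]; each bin's value is the summed proportion of
    clones falling in it, so values sum to 1.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing (overlapping or unordered bins)")
    if edges[0] != 0.0 or edges[-1] != 1.0:
        raise ValueError("bins must cover (0, 1]: first edge 0, last edge 1")
    p = rep.proportions
    # right-closed: bin i holds p with edges[i] < p <= edges[i+1]
    idx = np.searchsorted(edges, p, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    result = {}
    for i in range(len(edges) - 1):
        result[(float(edges[i]), float(edges[i + 1]))] = float(p[idx == i].sum())
    return result


def classify_clones(
    rep: Repertoire, dominant_prop: float = 0.01, dominant_n: int = 50
) -> list[CloneClass]:
    """Singlet (n_c = 1) vs expanded (n_c > 1); dominant when the clonal
    proportion exceeds ``dominant_prop`` AND the count exceeds ``dominant_n``
    (both strict)."""
    if dominant_prop <= 0 or dominant_n <= 0:
        raise ValueError("dominance thresholds must be positive")
    N = rep.N
    out = []
    for clone in rep.clonotypes:
        n = clone.n_c
        p = n / N
        cls = "singlet" if n == 1 else "expanded"
        dominant = (p > dominant_prop) and (n > dominant_n)
        out.append(CloneClass(clone.key, n, p, cls, dominant))
    return out


def cell_class_table(rep: Repertoire, classes: Sequence[CloneClass] | None = None) -> pd.DataFrame:
    """Per-cell view of clone classification (barcode, class, dominant)."""
    if classes is None:
        classes = classify_clones(rep)
    by_key = {c.key: c for c in classes}
    rows = []
    for clone in rep.clonotypes:
        cc = by_key[clone.key]
        for barcode in sorted(clone.cells):
            rows.append(
                {
                    "cell_barcode": barcode,
                    "sample_id": rep.sample_id,
                    "clone_class": cc.clone_class,
                    "dominant": cc.dominant,
                    "n_c": cc.n_c,
                    "proportion": cc.proportion,
                }
            )
    return pd.DataFrame(rows)
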