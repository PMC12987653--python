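"""Group contrasts: differential expression, preranked gene-set enrichment,
and cell-type proportion comparison.

DGE uses the two-sided Wilcoxon rank-sum test on library-size-normalized
log expression with Benjamini-Hochberg correction within each contrast.
Gene-set enrichment follows the weighted Kolmogorov-Smirnov running-sum
statistic (ES), normalized against a gene-label permutation null (NES) with
permutation-based nominal p and FDR q.  Cell-type proportions are compared
on the variance-stabilizing arcsine-square-root scale,
delta = asin(sqrt(p_a)) - asin(sqrt(p_b)), with analytic normal CIs from
var(asin(sqrt(p_hat))) ~= 1/(4n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mosaicism import CellVariantCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastSpec:
    """Two disjoint, tissue-matched cell groups to be contrasted."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    tissue: str
    label: str

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.label!r}: both groups must be nonempty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.label!r}: groups must be disjoint")


def normalize_counts(raw: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalization: x = ln(1 + scale * c / total_per_cell).

    Cells with zero total counts are excluded (logged).
    """
    totals = raw.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("all cells have zero total counts")
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.info("excluding %d zero-total cells from normalization", n_zero)
    kept = raw.loc[totals > 0]
    x = np.log1p(scale * kept.div(kept.sum(axis=1), axis=0))
    return x


@dataclass
class DGEResult:
    contrast: str
    table: pd.DataFrame  # gene, lfc, stat, p, q, frac_a, frac_b
    n_a: int
    n_b: int
    n_genes_tested: int


def dge(
    spec: ContrastSpec,
    expr: pd.DataFrame,
    min_frac: float = 0.1,
    pseudocount: float = 1e-9,
) -> DGEResult:
    """Per-gene two-sided Wilcoxon rank-sum between the contrast's groups.

    Genes expressed in fewer than ``min_frac`` of cells in both groups are
    dropped before testing; q values are Benjamini-Hochberg over the tested
    genes; lfc = log2((mean_A + pc) / (mean_B + pc)) on de-logged
    normalized expression.
    """
    a = expr.loc[expr.index.intersection(spec.group_a)]
    b = expr.loc[expr.index.intersection(spec.group_b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"underpowered contrast {spec.label!r}: group sizes {len(a)}, {len(b)}")
    frac_a = (a > 0).mean(axis=0)
    frac_b = (b > 0).mean(axis=0)
    keep = (frac_a >= min_frac) | (frac_b >= min_frac)
    genes = expr.columns[keep]
    if len(genes) == 0:
        raise ValueError(f"contrast {spec.label!r}: no genes pass min_frac={min_frac}")
    xa = a[genes].to_numpy(float)
    xb = b[genes].to_numpy(float)
    res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided", method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # all-tied genes: no evidence
    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    q = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": genes,
            "lfc": lfc,
            "stat": np.asarray(res.statistic, dtype=float),
            "p": pvals,
            "q": q,
            "frac_a": frac_a[genes].to_numpy(),
            "frac_b": frac_b[genes].to_numpy(),
        }
    ).reset_index(drop=True)
    return DGEResult(spec.label, table, len(a), len(b), len(genes))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p values (delegates to statsmodels)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


# --- preranked GSEA -------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    flags: tuple[str, ...] = ()


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n_genes: int):
    """Signed enrichment score(s) from sorted hit positions.

    ``pos`` is (B, k) of 0-based hit positions into the ranked list (sorted
    ascending along axis 1); ``weights`` is |score|^w over all ranked genes.
    Returns (es, argext) where argext is the hit rank index (0..k-1) at
    which the extreme deviation occurs, for leading-edge extraction.
    """
    pos = np.atleast_2d(pos)
    B, k = pos.shape
    if k == n_genes:
        return np.zeros(B), np.zeros(B, dtype=int)
    d = 1.0 / (n_genes - k)
    w = weights[pos]
    sumw = w.sum(axis=1, keepdims=True)
    # degenerate all-zero hit weights: fall back to unweighted hits
    zero = (sumw == 0).ravel()
    if zero.any():
        w = w.copy()
        w[zero] = 1.0
        sumw = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1) / sumw
    j = np.arange(k)
    # running sum just after hit j, and just before hit j
    after = cumw - (pos - j) * d
    before = np.concatenate([np.zeros((B, 1)), cumw[:, :-1]], axis=1) - (pos - j) * d
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    arg_hi = after.argmax(axis=1)
    arg_lo = before.argmin(axis=1)
    rows = np.arange(B)
    # on a magnitude tie (up to rounding) the extreme reached first in the
    # walk wins: the positive candidate sits at walk index pos[arg_hi], the
    # negative one just before pos[arg_lo]
    tied = np.isclose(hi, -lo, rtol=1e-9, atol=1e-12)
    use_hi = np.where(tied, pos[rows, arg_hi] < pos[rows, arg_lo], hi > -lo)
    es = np.where(use_hi, hi, lo)
    argext = np.where(use_hi, arg_hi, arg_lo)
    return es, argext


def enrichment_score(
    ranking: pd.Series, gene_set: set[str], weight: float = 1.0
) -> tuple[float, tuple[str, ...]]:
    """ES of one gene set against a signed ranking (descending by score).

    Hits increment the running sum by |score|^weight normalized over hits;
    misses decrement by 1/(n_genes - n_hits); the ES is the extreme
    deviation.  Returns (es, leading_edge genes).  A set covering every
    ranked gene is degenerate and scores 0.
    """
    ranking = ranking.sort_values(ascending=False, kind="mergesort")
    genes = ranking.index.to_numpy()
    hit_mask = np.isin(genes, list(gene_set))
    pos = np.flatnonzero(hit_mask)
    if pos.size == 0:
        return 0.0, ()
    n = len(genes)
    if pos.size == n:
        return 0.0, ()
    weights = np.abs(ranking.to_numpy()) ** weight
    es, argext = _es_from_positions(pos[None, :], weights, n)
    es, argext = float(es[0]), int(argext[0])
    if es >= 0:
        le = genes[pos[: argext + 1]]
    else:
        le = genes[pos[argext:]]
    return es, tuple(le)


def gsea_preranked(
    ranking: pd.Series,
    sets: dict[str, set[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Preranked GSEA with a gene-label permutation null.

    Every set is intersected with the ranked genes; sets below ``min_size``
    are skipped (logged).  NES = ES / mean(|null ES of same sign|); nominal
    p is the fraction of same-sign null ES at least as extreme (add-one
    smoothed); FDR q follows the permutation NES tail-ratio procedure,
    clipped to [0, 1].
    """
    if ranking.index.has_duplicates:
        raise ValueError("ranking genes must be unique")
    if not np.isfinite(ranking.to_numpy()).all():
        raise ValueError("ranking scores must be finite")
    ranking = ranking.sort_values(ascending=False, kind="mergesort")
    genes = ranking.index.to_numpy()
    n = len(genes)
    weights = np.abs(ranking.to_numpy()) ** weight
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in sets.items():
        pos = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        if pos.size < min_size:
            logger.info("skipping set %s: %d genes in ranking < min_size %d", name, pos.size, min_size)
            continue
        kept.append((name, pos))
    if not kept:
        return []

    # one permutation null per distinct set size (a random gene-label
    # permutation is equivalent to a uniform random set of the same size)
    null_by_size: dict[int, np.ndarray] = {}
    for _name, pos in kept:
        k = pos.size
        if k in null_by_size or k == n:
            continue
        r = rng.random((n_perm, n))
        idx = np.argpartition(r, k - 1, axis=1)[:, :k]
        idx.sort(axis=1)
        null_by_size[k], _ = _es_from_positions(idx, weights, n)

    results: list[EnrichmentResult] = []
    obs_nes = []
    null_nes_pool = []
    for name, pos in kept:
        k = pos.size
        flags: list[str] = []
        es, argext = _es_from_positions(pos[None, :], weights, n)
        es, argext = float(es[0]), int(argext[0])
        if k == n:
            flags.append("degenerate_all_genes")
            results.append(EnrichmentResult(name, k, 0.0, 0.0, 1.0, 1.0, (), tuple(flags)))
            continue
        null = null_by_size[k]
        same = null[null > 0] if es >= 0 else null[null < 0]
        mean_same = np.abs(same).mean() if same.size else np.nan
        nes = es / mean_same if same.size and mean_same > 0 else 0.0
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size) if same.size else 1.0
        if es >= 0:
            le = tuple(genes[pos[: argext + 1]])
        else:
            le = tuple(genes[pos[argext:]])
        # normalized null for the pooled FDR computation
        pos_null = null[null > 0]
        neg_null = null[null < 0]
        norm = np.concatenate(
            [
                pos_null / pos_null.mean() if pos_null.size else pos_null,
                neg_null / np.abs(neg_null).mean() if neg_null.size else neg_null,
            ]
        )
        null_nes_pool.append(norm)
        obs_nes.append(nes)
        results.append(EnrichmentResult(name, k, es, nes, float(p), np.nan, le, tuple(flags)))

    # permutation-based FDR over the pooled normalized null
    if null_nes_pool:
        pool = np.concatenate(null_nes_pool)
        obs = np.array(obs_nes)
        finals = []
        j = 0
        for res in results:
            if "degenerate_all_genes" in res.flags:
                finals.append(res)
                continue
            nes = obs[j]
            j += 1
            if nes >= 0:
                null_tail = np.mean(pool >= nes) if (pool > 0).any() else 0.0
                null_sign = np.mean(pool > 0)
                obs_tail = np.mean(obs >= nes)
                obs_sign = np.mean(obs > 0)
            else:
                null_tail = np.mean(pool <= nes) if (pool < 0).any() else 0.0
                null_sign = np.mean(pool < 0)
                obs_tail = np.mean(obs <= nes)
                obs_sign = np.mean(obs < 0)
            num = null_tail / null_sign if null_sign > 0 else 0.0
            den = obs_tail / obs_sign if obs_sign > 0 else 1.0
            q = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
            finals.append(
                EnrichmentResult(res.set_name, res.size, res.es, res.nes, res.p, q,
                                 res.leading_edge, res.flags)
            )
        results = finals
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p": r.p,
                "fdr_q": r.fdr_q,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ]
    )


# --- cell-type proportion comparison --------------------------------------


@dataclass(frozen=True)
class ProportionComparison:
    cell_type: str
    group: str
    reference_group: str
    p_a: float
    p_b: float
    delta: float  # asin(sqrt(p_a)) - asin(sqrt(p_b))
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int


def proportion_forest(
    annotations: pd.DataFrame,
    reference_group: str,
    ci: float = 0.95,
) -> list[ProportionComparison]:
    """Arcsine-square-root cell-type abundance differences versus a reference.

    For each comparison group and cell type, delta = asin(sqrt(p_a)) -
    asin(sqrt(p_b)) per (comparison sample, reference sample) pair, with
    analytic variance 1/(4 n_a) + 1/(4 n_b); multiple pairs are averaged
    with combined variance sum(var)/M^2.  Cell types absent from both
    groups are omitted.
    """
    groups = annotations["group"].unique()
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    z = stats.norm.ppf(0.5 + ci / 2.0)

    def _sample_props(df: pd.DataFrame) -> dict[str, pd.Series]:
        out = {}
        for sample, grp in df.groupby("sample_id"):
            out[sample] = grp["cell_type"].value_counts(normalize=True)
        return out

    ref_props = _sample_props(annotations[annotations["group"] == reference_group])
    ref_sizes = annotations[annotations["group"] == reference_group].groupby("sample_id").size()

    results = []
    for group in sorted(g for g in groups if g != reference_group):
        sub = annotations[annotations["group"] == group]
        comp_props = _sample_props(sub)
        comp_sizes = sub.groupby("sample_id").size()
        cell_types = sorted(
            set(sub["cell_type"]) | set().union(*(set(p.index) for p in ref_props.values()))
        )
        for ct in cell_types:
            deltas, variances, pa_vals, pb_vals = [], [], [], []
            for sa, props_a in comp_props.items():
                for sb, props_b in ref_props.items():
                    pa = float(props_a.get(ct, 0.0))
                    pb = float(props_b.get(ct, 0.0))
                    na, nb = int(comp_sizes[sa]), int(ref_sizes[sb])
                    deltas.append(np.arcsin(np.sqrt(pa)) - np.arcsin(np.sqrt(pb)))
                    variances.append(1.0 / (4 * na) + 1.0 / (4 * nb))
                    pa_vals.append(pa)
                    pb_vals.append(pb)
            if not deltas:
                continue
            m = len(deltas)
            delta = float(np.mean(deltas))
            se = float(np.sqrt(np.sum(variances)) / m)
            results.append(
                ProportionComparison(
                    cell_type=ct,
                    group=group,
                    reference_group=reference_group,
                    p_a=float(np.mean(pa_vals)),
                    p_b=float(np.mean(pb_vals)),
                    delta=delta,
                    ci_low=delta - z * se,
                    ci_high=delta + z * se,
                    n_a=int(comp_sizes.sum()),
                    n_b=int(ref_sizes.sum()),
                )
            )
    return results


def proportion_table(results: list[ProportionComparison]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# --- contrast construction -------------------------------------------------


def build_contrasts(
    cell_classes: pd.DataFrame,
    calls: list[CellVariantCall],
    annotations: pd.DataFrame,
    patient_group: str = "AGLCD",
    tissue_controls: dict[str, str] | None = None,
) -> list[ContrastSpec]:
    """Assemble the tissue-matched contrast families.

    Per tissue: (1) patient expanded-clone cells vs all control-group cells;
    (2) mutant cells vs intra-patient cells with no detectable mutant UMIs
    (wildtype-covered); (3) mutant cells vs control-group cells.  Contrasts
    whose groups come up empty are skipped with a warning.
    """
    if tissue_controls is None:
        tissue_controls = {"blood": "HD", "gut": "CD"}
    ann = annotations.set_index("cell_barcode")
    expanded = set(cell_classes.loc[cell_classes["clone_class"] == "expanded", "cell_barcode"])
    mutant = {c.cell_barcode for c in calls if c.genotype_class == "mutant"}
    wt_covered = {c.cell_barcode for c in calls if c.genotype_class == "wildtype_covered"}

    specs: list[ContrastSpec] = []
    for tissue, control_group in tissue_controls.items():
        in_tissue = ann[ann["tissue"] == tissue]
        patient_cells = set(in_tissue.index[in_tissue["group"] == patient_group])
        control_cells = tuple(sorted(in_tissue.index[in_tissue["group"] == control_group]))
        candidates = [
            (f"expanded_vs_{control_group}_{tissue}",
             tuple(sorted(expanded & patient_cells)), control_cells),
            (f"mutant_vs_nonmutant_{tissue}",
             tuple(sorted(mutant & patient_cells)),
             tuple(sorted(wt_covered & patient_cells))),
            (f"mutant_vs_{control_group}_{tissue}",
             tuple(sorted(mutant & patient_cells)), control_cells),
        ]
        for label, a, b in candidates:
            if not a or not b:
                logger.warning("skipping contrast %s: empty group", label)
                continue
            specs.append(ContrastSpec(a, b, tissue, label))
    return specs
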