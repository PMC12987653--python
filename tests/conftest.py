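"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(per-base reference walks, explicit running sums, step-up loops, cell-label
permutation subsampling) so the package implementations are checked against
something that shares none of their code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from clonomosaic.io_formats import VariantLocus


# --- oracle: per-base CIGAR reference walk --------------------------------

def brute_force_reference_map(cigartuples, reference_start):
    """Map reference position -> query index (or "del"), one base at a time.

    Walks every CIGAR op base by base with no shortcuts; N (ref skip) bases
    are absent from the map entirely (not covered).
    """
    out = {}
    rpos, qpos = reference_start, 0
    for op, length in cigartuples:
        for _ in range(length):
            if op in (0, 7, 8):  # M, =, X
                out[rpos] = qpos
                rpos += 1
                qpos += 1
            elif op == 2:  # D
                out[rpos] = "del"
                rpos += 1
            elif op == 3:  # N
                rpos += 1
            elif op in (1, 4):  # I, S
                qpos += 1
            # H, P: nothing
    return out


def brute_force_allele(aln, pos0):
    ref_map = brute_force_reference_map(aln.cigartuples, aln.reference_start)
    hit = ref_map.get(pos0)
    if hit is None:
        return None
    if hit == "del":
        return "del"
    return aln.query_sequence[hit].upper()


# --- oracle: GSEA running sum ---------------------------------------------

def brute_force_es(scores: pd.Series, gene_set: set, weight: float = 1.0) -> float:
    """Explicit running-sum enrichment score over a small ranked list."""
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    genes = list(ranked.index)
    hits = [g in gene_set for g in genes]
    n_hits = sum(hits)
    n = len(genes)
    if n_hits == 0 or n_hits == n:
        return 0.0
    wsum = sum(abs(ranked[g]) ** weight for g, h in zip(genes, hits) if h)
    run = 0.0
    best = 0.0
    for g, h in zip(genes, hits):
        if h:
            run += (abs(ranked[g]) ** weight) / wsum if wsum > 0 else 1.0 / n_hits
        else:
            run -= 1.0 / (n - n_hits)
        # first extreme wins at magnitude ties (up to accumulation rounding)
        if abs(run) > abs(best) * (1 + 1e-9) + 1e-12:
            best = run
    return best


def es_extremes_tied(scores: pd.Series, gene_set: set, weight: float = 1.0) -> bool:
    """True when the maximal positive and negative running-sum deviations tie
    in magnitude — the degenerate case where the ES sign is ambiguous."""
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    genes = list(ranked.index)
    hits = [g in gene_set for g in genes]
    n_hits = sum(hits)
    n = len(genes)
    if n_hits in (0, n):
        return True
    wsum = sum(abs(ranked[g]) ** weight for g, h in zip(genes, hits) if h)
    run, hi, lo = 0.0, 0.0, 0.0
    for g, h in zip(genes, hits):
        if h:
            run += (abs(ranked[g]) ** weight) / wsum if wsum > 0 else 1.0 / n_hits
        else:
            run -= 1.0 / (n - n_hits)
        hi = max(hi, run)
        lo = min(lo, run)
    return bool(np.isclose(hi, -lo, rtol=1e-9, atol=1e-12))


# --- oracle: BH step-up ----------------------------------------------------

def brute_force_bh(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


# --- oracle: permutation-label subsampling --------------------------------

def permutation_subsample_inverse_simpson(counts, depth, n_draws, rng):
    """Expected inverse Simpson at a downsampling depth, estimated by drawing
    cells as explicit labels via permutation (independent of the package's
    hypergeometric sampler)."""
    labels = np.repeat(np.arange(len(counts)), counts)
    n_clones = len(counts)
    vals = np.empty(n_draws)
    for b in range(n_draws):
        take = rng.choice(labels, size=depth, replace=False)
        c = np.bincount(take, minlength=n_clones)
        p = c / depth
        vals[b] = 1.0 / np.square(p).sum()
    return vals


# --- oracle: Pearson from explicit sums -----------------------------------

def spreadsheet_pearson(x, y):
    """Pearson r via explicit sums, the way a spreadsheet computes it."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


# --- SAM fixture writer ----------------------------------------------------

def write_sam(path, reads, contig="chrT", length=500):
    """Write hand-specified reads to a SAM file.

    Each read is a dict with keys: name, start (0-based), cigar, seq, and
    optional flag, cb, ub.
    """
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": length}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for spec in reads:
            a = pysam.AlignedSegment()
            a.query_name = spec["name"]
            a.query_sequence = spec["seq"]
            a.flag = spec.get("flag", 0)
            a.reference_id = 0
            a.reference_start = spec["start"]
            a.mapping_quality = 60
            a.cigarstring = spec["cigar"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(spec["seq"]))
            if "cb" in spec:
                a.set_tag("CB", spec["cb"])
            if "ub" in spec:
                a.set_tag("UB", spec["ub"])
            out.write(a)
    return path


@pytest.fixture
def toy_locus():
    return VariantLocus("chrT", 101, "G", "A", "toy")
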