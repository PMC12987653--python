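"""Cross-sample clonotype overlap, persistence, and abundance concordance.

Repertoires built under the same clonotype scheme are joined on clonotype
key; overlap is summarized by exact-presence-pattern (upset) counts and
abundance concordance by Pearson correlation of log10 clone proportions,
with a pseudocount for clones absent from one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clonality import CloneClass, Repertoire, classify_clones

logger = logging.getLogger(__name__)


@dataclass
class SharedCloneMap:
    """Full outer join of repertoires on clonotype key.

    ``counts`` has one row per clonotype in the union and one column per
    sample (0 where absent); ``totals`` holds each sample's cell count N_s.
    """

    counts: pd.DataFrame
    totals: dict[str, int]
    scheme: str

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts / pd.Series(self.totals)

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def n_union(self) -> int:
        return len(self.counts)

    def n_shared(self) -> int:
        return int((self.presence.sum(axis=1) >= 2).sum())

    def pair_categories(self, sample_a: str, sample_b: str) -> pd.DataFrame:
        """Per-clone category for a sample pair: {exclusive,shared}_{singlet,expanded}.

        A clone is shared when present in both samples; the singlet/expanded
        label is reported per member sample (singlet iff n = 1 there).
        """
        sub = self.counts[[sample_a, sample_b]]
        sub = sub[(sub > 0).any(axis=1)]
        shared = (sub > 0).all(axis=1)
        out = pd.DataFrame(index=sub.index)
        for s in (sample_a, sample_b):
            labels = []
            for n, is_shared in zip(sub[s], shared):
                if n == 0:
                    labels.append("absent")
                else:
                    prefix = "shared" if is_shared else "exclusive"
                    labels.append(f"{prefix}_{'singlet' if n == 1 else 'expanded'}")
            out[f"category_{s}"] = labels
        out["shared"] = shared
        return out


def join_repertoires(reps: Sequence[Repertoire]) -> SharedCloneMap:
    """Outer-join >= 2 repertoires (same clonotype scheme) on clonotype key."""
    if len(reps) < 2:
        raise ValueError("need at least two repertoires to join")
    schemes = {r.scheme for r in reps}
    if len(schemes) > 1:
        raise ValueError(f"cannot join repertoires built under mixed clonotype schemes: {schemes}")
    ids = [r.sample_id for r in reps]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique across joined repertoires")
    series = []
    for rep in reps:
        # object index of key tuples (tupleize_cols=False avoids a MultiIndex)
        idx = pd.Index([c.key for c in rep.clonotypes], dtype=object, tupleize_cols=False)
        s = pd.Series([c.n_c for c in rep.clonotypes], index=idx, name=rep.sample_id)
        series.append(s)
    counts = pd.concat(series, axis=1).fillna(0).astype(np.int64)
    order = sorted(counts.index, key=lambda k: tuple("" if f is None else str(f) for f in k))
    counts = counts.reindex(order)
    return SharedCloneMap(counts, {r.sample_id: r.N for r in reps}, scheme=reps[0].scheme)


def upset_counts(scmap: SharedCloneMap) -> dict[tuple[str, ...], int]:
    """Clonotype counts per exact presence pattern (upset-plot semantics).

    Each clone is counted once, in the cell of the sample subset it is
    present in exactly; counts over all non-empty subsets sum to n_union.
    """
    presence = scmap.presence
    patterns = presence.apply(lambda row: tuple(s for s in scmap.samples if row[s]), axis=1)
    out: dict[tuple[str, ...], int] = {}
    for pattern, n in patterns.value_counts().items():
        out[pattern] = int(n)
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    sample_a: str
    sample_b: str
    n_union: int
    n_shared: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    transform: str
    pseudocount: float
    n_points: int
    flags: tuple[str, ...] = ()


def concordance(
    scmap: SharedCloneMap,
    sample_a: str | None = None,
    sample_b: str | None = None,
    pseudocount: float = 0.5,
    scope: str = "union",
) -> ConcordanceResult:
    """Pearson concordance of log10 clone proportions between two samples.

    x = log10(p) for present clones; absent clones (scope="union" only)
    enter at log10(pseudocount / N_s).  A global least-squares line is
    fitted through the same points.  Fewer than 3 points in scope yields a
    result flagged "insufficient_points" with undefined r.
    """
    if scope not in ("union", "shared"):
        raise ValueError(f"scope must be 'union' or 'shared', got {scope!r}")
    samples = scmap.samples
    if sample_a is None or sample_b is None:
        if len(samples) != 2:
            raise ValueError("specify sample_a/sample_b when the map has more than two samples")
        sample_a, sample_b = samples
    sub = scmap.counts[[sample_a, sample_b]]
    sub = sub[(sub > 0).any(axis=1)]
    n_union = len(sub)
    present_both = (sub > 0).all(axis=1)
    n_shared = int(present_both.sum())
    if scope == "shared":
        sub = sub[present_both]

    flags: list[str] = []
    na, nb = scmap.totals[sample_a], scmap.totals[sample_b]

    def _log_prop(counts: pd.Series, n_total: int) -> np.ndarray:
        p = counts.to_numpy(float) / n_total
        q = pseudocount / n_total
        return np.log10(np.where(p > 0, p, q))

    x = _log_prop(sub[sample_a], na)
    y = _log_prop(sub[sample_b], nb)
    n_points = len(x)
    if n_points < 3:
        flags.append("insufficient_points")
        r = slope = intercept = float("nan")
    elif np.ptp(x) == 0 or np.ptp(y) == 0:
        flags.append("degenerate_variance")
        r = slope = intercept = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
        if scope == "union" and n_shared == 0:
            flags.append("low_overlap")
    return ConcordanceResult(
        sample_a=sample_a,
        sample_b=sample_b,
        n_union=n_union,
        n_shared=n_shared,
        pearson_r=r,
        r_squared=r * r if np.isfinite(r) else float("nan"),
        slope=slope,
        intercept=intercept,
        transform="log10(proportion), pseudocount on absent clones",
        pseudocount=pseudocount,
        n_points=n_points,
        flags=tuple(flags),
    )


@dataclass
class PersistenceReport:
    """Pairwise concordance and clone re-detection for one subject's samples."""

    concordance_t1_t2: ConcordanceResult
    concordance_blood_gut: ConcordanceResult
    shared_t1_t2: pd.DataFrame
    shared_blood_gut: pd.DataFrame
    redetected_t2_fraction: float
    redetected_gut_fraction: float
    n_t1_expanded: int


def persistence_report(
    blood_t1: Repertoire,
    blood_t2: Repertoire,
    gut: Repertoire,
    pseudocount: float = 0.5,
    scope: str = "union",
) -> PersistenceReport:
    """Long-term persistence of a subject's expanded blood clones.

    Reports T1-T2 and blood-gut concordance, shared-clone tables, and the
    fraction of T1-expanded clonotypes re-detected at T2 and in the gut.
    """
    join12 = join_repertoires([blood_t1, blood_t2])
    join1g = join_repertoires([blood_t1, gut])
    conc12 = concordance(join12, pseudocount=pseudocount, scope=scope)
    conc1g = concordance(join1g, pseudocount=pseudocount, scope=scope)

    t1_expanded = {c.key for c in classify_clones(blood_t1) if c.clone_class == "expanded"}
    t2_keys = {c.key for c in blood_t2.clonotypes}
    gut_keys = {c.key for c in gut.clonotypes}
    n_exp = len(t1_expanded)
    frac_t2 = len(t1_expanded & t2_keys) / n_exp if n_exp else float("nan")
    frac_gut = len(t1_expanded & gut_keys) / n_exp if n_exp else float("nan")

    def _shared_table(scmap: SharedCloneMap) -> pd.DataFrame:
        a, b = scmap.samples
        tbl = scmap.counts.copy()
        cats = scmap.pair_categories(a, b)
        return tbl.join(cats)

    return PersistenceReport(
        concordance_t1_t2=conc12,
        concordance_blood_gut=conc1g,
        shared_t1_t2=_shared_table(join12),
        shared_blood_gut=_shared_table(join1g),
        redetected_t2_fraction=frac_t2,
        redetected_gut_fraction=frac_gut,
        n_t1_expanded=n_exp,
    )


def shared_clone_table(scmap: SharedCloneMap) -> pd.DataFrame:
    """Flat TSV-ready table: clonotype key fields, per-sample counts, pattern."""
    counts = scmap.counts
    keys = pd.DataFrame(
        list(counts.index),
        columns=["v_tra", "j_tra", "cdr3_nt_tra", "v_trb", "j_trb", "cdr3_nt_trb"],
    )
    body = counts.reset_index(drop=True)
    pattern = scmap.presence.apply(
        lambda row: "+".join(s for s in scmap.samples if row[s]), axis=1
    ).reset_index(drop=True)
    out = pd.concat([keys, body], axis=1)
    out["pattern"] = pattern
    return out
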