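"""Per-cell detection of a somatic point mutation in barcode-tagged reads.

Reads spanning the variant locus are grouped by (cell barcode, UMI); each
UMI contributes one consensus allele (majority vote over its reads, ties
ambiguous), so PCR duplicates cannot inflate the evidence.  A cell is
called mutant when it carries at least ``alt_min`` alternate-allele UMIs,
wildtype-covered when it has reference UMIs and no alternate UMIs, and
uncovered when no UMI spans the locus.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import VariantLocus

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("mutant", "wildtype_covered", "uncovered", "ambiguous")


@dataclass(frozen=True)
class CellVariantCall:
    cell_barcode: str
    locus_label: str
    n_umi_ref: int
    n_umi_alt: int
    n_umi_other: int
    genotype_class: str

    def __post_init__(self) -> None:
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValueError(f"unknown genotype class {self.genotype_class!r}")


def collapse_umis(
    stream: Iterable[tuple[str, str, str]]
) -> dict[str, Counter]:
    """Collapse read-level allele observations to per-cell UMI consensus counts.

    Reads are grouped by (cell, UMI); each UMI's consensus allele is the
    majority vote over its reads, with exact ties collapsing to
    ``"ambiguous"``.  Returns {barcode: Counter(consensus allele -> n UMIs)}.
    """
    votes: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for barcode, umi, allele in stream:
        votes[(barcode, umi)][allele] += 1
    per_cell: dict[str, Counter] = defaultdict(Counter)
    for (barcode, _umi), counts in votes.items():
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            consensus = "ambiguous"
        else:
            consensus = top[0][0]
        per_cell[barcode][consensus] += 1
    return dict(per_cell)


def call_cells(
    umi_counts: dict[str, Counter],
    locus: VariantLocus,
    alt_min: int = 1,
    error_rate: float | None = None,
) -> list[CellVariantCall]:
    """Classify each covered cell by its allele UMI evidence at the locus.

    mutant: n_alt >= alt_min; wildtype_covered: n_alt = 0 and n_ref >= 1;
    ambiguous: only other/ambiguous UMIs (or alternate evidence below
    alt_min).  Cells absent from ``umi_counts`` are uncovered and appear
    only when merged with annotations in :func:`summarize_mosaicism`.

    When ``error_rate`` (per-base substitution probability, uniform over
    the three alternatives) is given, the per-cell binomial false-positive
    probability P(>= alt_min alt UMIs | true WT) is logged.
    """
    if alt_min < 1:
        raise ValueError("alt_min must be >= 1")
    calls = []
    for barcode in sorted(umi_counts):
        counts = umi_counts[barcode]
        n_ref = counts.get(locus.ref_allele, 0)
        n_alt = counts.get(locus.alt_allele, 0)
        n_other = sum(counts.values()) - n_ref - n_alt
        if n_alt >= alt_min:
            cls = "mutant"
        elif n_alt == 0 and n_ref >= 1:
            cls = "wildtype_covered"
        elif n_ref + n_alt + n_other == 0:
            cls = "uncovered"
        else:
            cls = "ambiguous"
        if error_rate is not None and cls == "mutant":
            k = n_ref + n_alt + n_other
            fp = float(stats.binom.sf(alt_min - 1, k, error_rate / 3.0))
            logger.info(
                "cell %s called mutant (%d/%d alt UMIs); P(false positive | WT) = %.3g",
                barcode, n_alt, k, fp,
            )
        calls.append(
            CellVariantCall(barcode, locus.label or f"{locus.contig}:{locus.position}",
                            n_ref, n_alt, n_other, cls)
        )
    return calls


def calls_table(calls: list[CellVariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_barcode": c.cell_barcode,
                "locus": c.locus_label,
                "n_umi_ref": c.n_umi_ref,
                "n_umi_alt": c.n_umi_alt,
                "n_umi_other": c.n_umi_other,
                "genotype_class": c.genotype_class,
            }
            for c in calls
        ]
    )


def summarize_mosaicism(
    calls: list[CellVariantCall], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate per-cell calls over (sample, cell type).

    Annotated cells without any covering UMI are counted as uncovered; calls
    whose barcode is not annotated are dropped (logged).  The mutant
    fraction is computed among covered cells (mutant + wildtype_covered)
    and reported as NaN when no cell is covered.
    """
    by_barcode = {c.cell_barcode: c for c in calls}
    annotated = set(annotations["cell_barcode"])
    unmatched = [b for b in by_barcode if b not in annotated]
    if unmatched:
        logger.warning("dropping %d called cells absent from annotations", len(unmatched))
    if len(unmatched) == len(by_barcode) and by_barcode:
        raise ValueError("no overlap between called barcodes and annotations")

    rows = []
    for (sample, cell_type), grp in annotations.groupby(["sample_id", "cell_type"], sort=True):
        n = {"mutant": 0, "wildtype_covered": 0, "uncovered": 0, "ambiguous": 0}
        for barcode in grp["cell_barcode"]:
            call = by_barcode.get(barcode)
            n[call.genotype_class if call else "uncovered"] += 1
        covered = n["mutant"] + n["wildtype_covered"]
        rows.append(
            {
                "sample_id": sample,
                "cell_type": cell_type,
                "n_cells": int(len(grp)),
                "n_mutant": n["mutant"],
                "n_wildtype_covered": n["wildtype_covered"],
                "n_uncovered": n["uncovered"],
                "n_ambiguous": n["ambiguous"],
                "n_covered": covered,
                "mutant_fraction": n["mutant"] / covered if covered else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def expected_false_positive_rate(umi_depths: np.ndarray, error_rate: float, alt_min: int = 1) -> float:
    """Mean P(>= alt_min alternate UMIs | true WT) over cells with the given
    locus UMI depths, under a uniform substitution model (per-allele error
    rate error_rate / 3)."""
    k = np.asarray(umi_depths, dtype=int)
    eps = error_rate / 3.0
    return float(np.mean(stats.binom.sf(alt_min - 1, k, eps)))
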