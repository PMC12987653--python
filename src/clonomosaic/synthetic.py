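"""Ground-truthed synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
heavy-tailed clone-size distributions with planted expanded clones, paired
repertoires with controlled sharing and latent log-abundance correlation,
barcode/UMI-tagged reads carrying a point mutation at a set cellular
genotype, and negative-binomial expression with planted fold-changes and
enriched gene sets — and emit files in the pipeline's standard formats
together with truth tables, so every downstream claim can be checked
without access to patient data.  All randomness flows from an explicit
seed; output files are byte-identical across runs at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from . import io_formats
from .io_formats import ClonotypeRecord, VariantLocus

_NT = np.array(list("ACGT"))

_TRBV = [f"TRBV{i}" for i in range(1, 21)]
_TRBJ = [f"TRBJ{i}-{j}" for i in range(1, 3) for j in range(1, 4)]
_TRAV = [f"TRAV{i}" for i in range(1, 21)]
_TRAJ = [f"TRAJ{i}" for i in range(1, 7)]


def _random_cdr3nt(rng: np.random.Generator, used: set[str]) -> str:
    """Distinct CDR3 nucleotide string, length divisible by 3."""
    while True:
        n_codons = int(rng.integers(5, 16))
        seq = "".join(rng.choice(_NT, size=3 * n_codons))
        if seq not in used:
            used.add(seq)
            return seq


def _clone_chains(rng: np.random.Generator, used: set[str]) -> dict:
    cdr3_trb = _random_cdr3nt(rng, used)
    cdr3_tra = _random_cdr3nt(rng, used)
    return {
        "v_trb": str(rng.choice(_TRBV)),
        "j_trb": str(rng.choice(_TRBJ)),
        "cdr3_trb": cdr3_trb,
        "cdr3_trb_aa": str(Seq(cdr3_trb).translate()),
        "v_tra": str(rng.choice(_TRAV)),
        "j_tra": str(rng.choice(_TRAJ)),
        "cdr3_tra": cdr3_tra,
        "cdr3_tra_aa": str(Seq(cdr3_tra).translate()),
    }


def _logseries_counts(rng: np.random.Generator, theta: float, n_cells: int) -> list[int]:
    """Clone counts from a log-series law, accumulated to exactly n_cells."""
    counts: list[int] = []
    total = 0
    while total < n_cells:
        batch = rng.logseries(theta, size=max(16, (n_cells - total) // 2))
        for c in batch:
            c = int(c)
            if total + c >= n_cells:
                c = n_cells - total
            counts.append(c)
            total += c
            if total >= n_cells:
                break
    return [c for c in counts if c > 0]


@dataclass
class RepertoireModel:
    """One sample's repertoire: log-series background + planted expanded clones."""

    n_cells: int = 3000
    theta: float = 0.96
    planted: tuple[float, ...] = (0.15, 0.08, 0.03)
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("log-series theta must be in (0, 1)")
        if sum(self.planted) >= 1:
            raise ValueError("planted proportions must sum to < 1")


@dataclass
class SimulatedRepertoire:
    airr_path: Path
    truth_path: Path
    truth: pd.DataFrame


def _materialize_airr(
    rng: np.random.Generator,
    clone_defs: list[dict],
    counts: list[int],
    sample_id: str,
    paired: bool,
) -> list[ClonotypeRecord]:
    records = []
    cell_no = 0
    for clone, n in zip(clone_defs, counts):
        for _ in range(n):
            barcode = f"{sample_id}-{cell_no:07d}"
            cell_no += 1
            records.append(
                ClonotypeRecord(
                    barcode, "TRB", clone["v_trb"], clone["j_trb"],
                    clone["cdr3_trb"], clone["cdr3_trb_aa"],
                    int(rng.poisson(2) + 1), True,
                )
            )
            if paired:
                records.append(
                    ClonotypeRecord(
                        barcode, "TRA", clone["v_tra"], clone["j_tra"],
                        clone["cdr3_tra"], clone["cdr3_tra_aa"],
                        int(rng.poisson(1) + 1), True,
                    )
                )
    return records


def simulate_repertoire(
    model: RepertoireModel, out_dir: str | Path, sample_id: str = "sample"
) -> SimulatedRepertoire:
    """Simulate one repertoire; write AIRR TSV + truth table.

    Planted clones get their target proportions exactly (rounded to cells);
    the remaining cells follow the log-series clone-size law.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(model.seed)
    planted_counts = [int(round(p * model.n_cells)) for p in model.planted]
    if any(c < 1 for c in planted_counts):
        raise ValueError("planted proportion too small to materialize at this n_cells")
    n_bg = model.n_cells - sum(planted_counts)
    bg_counts = _logseries_counts(rng, model.theta, n_bg)
    counts = planted_counts + bg_counts
    used: set[str] = set()
    clone_defs = [_clone_chains(rng, used) for _ in counts]
    records = _materialize_airr(rng, clone_defs, counts, sample_id, model.paired)
    airr_path = out_dir / f"{sample_id}.airr.tsv"
    io_formats.write_airr(records, airr_path)
    truth = pd.DataFrame(
        {
            "clone_id": [f"clone{i:05d}" for i in range(len(counts))],
            "cdr3_trb": [c["cdr3_trb"] for c in clone_defs],
            "count": counts,
            "planted": [i < len(planted_counts) for i in range(len(counts))],
            "target_prop": list(model.planted) + [np.nan] * len(bg_counts),
        }
    )
    truth_path = out_dir / f"{sample_id}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimulatedRepertoire(airr_path, truth_path, truth)


@dataclass
class PairedRepertoireModel:
    """Two samples with controlled clone sharing and latent abundance correlation."""

    n_clones: int = 600
    shared_fraction: float = 0.8
    rho: float = 0.8
    # depth: the latent log-abundance signal must dominate the multinomial
    # sampling noise (~1/count per clone on the log scale), which needs a
    # comfortable number of cells per clone
    n_cells: int = 30_000
    sigma: float = 1.0
    paired_chains: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must be in [-1, 1]")


@dataclass
class SimulatedPair:
    airr_paths: tuple[Path, Path]
    truth_path: Path
    truth: pd.DataFrame
    latent_correlation: float  # empirical Pearson r of (z1, z2) over shared clones


def simulate_paired_repertoires(
    model: PairedRepertoireModel, out_dir: str | Path, sample_ids: tuple[str, str] = ("T1", "T2")
) -> SimulatedPair:
    """Paired repertoires: shared clones carry bivariate-lognormal latent
    abundances with correlation rho before multinomial realization."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(model.seed)
    n_shared = int(round(model.shared_fraction * model.n_clones))
    n_excl = model.n_clones - n_shared
    n_excl_1 = n_excl // 2 + n_excl % 2
    n_excl_2 = n_excl // 2

    s2 = model.sigma**2
    cov = [[s2, model.rho * s2], [model.rho * s2, s2]]
    z_shared = rng.multivariate_normal([0.0, 0.0], cov, size=n_shared) if n_shared else np.empty((0, 2))
    z1_excl = rng.normal(0.0, model.sigma, size=n_excl_1)
    z2_excl = rng.normal(0.0, model.sigma, size=n_excl_2)

    abundance_1 = np.concatenate([np.exp(z_shared[:, 0]), np.exp(z1_excl), np.zeros(n_excl_2)])
    abundance_2 = np.concatenate([np.exp(z_shared[:, 1]), np.zeros(n_excl_1), np.exp(z2_excl)])
    counts_1 = rng.multinomial(model.n_cells, abundance_1 / abundance_1.sum())
    counts_2 = rng.multinomial(model.n_cells, abundance_2 / abundance_2.sum())

    used: set[str] = set()
    clone_defs = [_clone_chains(rng, used) for _ in range(model.n_clones)]
    airr_paths = []
    for sid, counts in zip(sample_ids, (counts_1, counts_2)):
        defs = [d for d, c in zip(clone_defs, counts) if c > 0]
        nonzero = [int(c) for c in counts if c > 0]
        records = _materialize_airr(rng, defs, nonzero, sid, model.paired_chains)
        path = Path(out_dir) / f"{sid}.airr.tsv"
        io_formats.write_airr(records, path)
        airr_paths.append(path)

    shared_flag = np.concatenate(
        [np.ones(n_shared, bool), np.zeros(n_excl, bool)]
    )
    z1 = np.concatenate([z_shared[:, 0], z1_excl, np.full(n_excl_2, np.nan)])
    z2 = np.concatenate([z_shared[:, 1], np.full(n_excl_1, np.nan), z2_excl])
    truth = pd.DataFrame(
        {
            "clone_id": [f"clone{i:05d}" for i in range(model.n_clones)],
            "cdr3_trb": [d["cdr3_trb"] for d in clone_defs],
            "shared": shared_flag,
            "z1": z1,
            "z2": z2,
            "count_1": counts_1,
            "count_2": counts_2,
        }
    )
    truth_path = Path(out_dir) / "paired.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    if n_shared >= 2:
        latent_r = float(np.corrcoef(z_shared[:, 0], z_shared[:, 1])[0, 1])
    else:
        latent_r = float("nan")
    return SimulatedPair(tuple(airr_paths), truth_path, truth, latent_r)


@dataclass
class ReadModel:
    """Barcode/UMI-tagged reads spanning a point-mutation locus."""

    n_cells: int = 1000
    mutant_fraction: float = 0.3
    coverage_lambda: float = 2.0  # locus UMIs per cell ~ Poisson
    reads_per_umi_extra: float = 0.0  # reads per UMI ~ 1 + Poisson(extra)
    error_rate: float = 0.0  # per-base substitution prob, uniform over 3 alts
    locus: VariantLocus = field(
        default_factory=lambda: VariantLocus("synthref1", 61, "G", "A", "G13D_synth")
    )
    read_length: int = 98
    ref_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if not 0 <= self.mutant_fraction <= 1:
            raise ValueError("mutant_fraction must be in [0, 1]")


@dataclass
class SimulatedReads:
    sam_path: Path
    truth_path: Path
    truth: pd.DataFrame


def simulate_reads(model: ReadModel, out_dir: str | Path) -> SimulatedReads:
    """Simulate a tagged SAM of reads spanning the locus, plus per-cell truth.

    Mutant cells emit the alternate allele, wildtype cells the reference,
    both corrupted by the per-base error model; every read covers the locus
    position.  The truth table stores each cell's true genotype and the
    post-error UMI-consensus allele counts (majority vote, ties ambiguous)
    — the generator's own bookkeeping, independent of the SAM parser.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(model.seed)
    locus = model.locus
    pos0 = locus.position - 1
    reference = rng.choice(_NT, size=model.ref_length)
    reference[pos0] = locus.ref_allele
    L = model.read_length
    lo = max(0, pos0 - L + 1)
    hi = min(pos0, model.ref_length - L)
    if hi < lo:
        raise ValueError("reference too short for the read length around the locus")

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": locus.contig, "LN": model.ref_length}],
    }
    sam_path = out_dir / "reads.sam"
    truth_rows = []
    other = {a: [b for b in "ACGT" if b != a] for a in "ACGT"}
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        read_no = 0
        for i in range(model.n_cells):
            barcode = f"CELL{i:06d}"
            is_mutant = bool(rng.random() < model.mutant_fraction)
            true_allele = locus.alt_allele if is_mutant else locus.ref_allele
            k = int(rng.poisson(model.coverage_lambda))
            consensus = {"ref": 0, "alt": 0, "other": 0}
            for j in range(k):
                umi = f"UMI{i:06d}X{j:03d}"
                n_reads = 1 + int(rng.poisson(model.reads_per_umi_extra)) if model.reads_per_umi_extra > 0 else 1
                read_alleles = []
                for _ in range(n_reads):
                    start = int(rng.integers(lo, hi + 1))
                    seq = reference[start : start + L].copy()
                    seq[pos0 - start] = true_allele
                    if model.error_rate > 0:
                        errs = np.flatnonzero(rng.random(L) < model.error_rate)
                        for e in errs:
                            seq[e] = other[str(seq[e])][int(rng.integers(3))]
                    read_alleles.append(str(seq[pos0 - start]))
                    aln = pysam.AlignedSegment()
                    aln.query_name = f"read{read_no:08d}"
                    read_no += 1
                    aln.query_sequence = "".join(seq)
                    aln.flag = 0
                    aln.reference_id = 0
                    aln.reference_start = start
                    aln.mapping_quality = 60
                    aln.cigarstring = f"{L}M"
                    aln.query_qualities = pysam.qualitystring_to_array("I" * L)
                    aln.set_tag("CB", barcode)
                    aln.set_tag("UB", umi)
                    out.write(aln)
                # generator-side UMI consensus (majority, tie -> ambiguous)
                vals, freq = np.unique(read_alleles, return_counts=True)
                top = freq.max()
                winners = vals[freq == top]
                if len(winners) > 1:
                    consensus["other"] += 1
                elif winners[0] == locus.alt_allele:
                    consensus["alt"] += 1
                elif winners[0] == locus.ref_allele:
                    consensus["ref"] += 1
                else:
                    consensus["other"] += 1
            truth_rows.append(
                {
                    "cell_barcode": barcode,
                    "genotype": "mutant" if is_mutant else "wildtype",
                    "n_umis": k,
                    "n_ref_umis": consensus["ref"],
                    "n_alt_umis": consensus["alt"],
                    "n_other_umis": consensus["other"],
                }
            )
    truth = pd.DataFrame(truth_rows)
    truth_path = out_dir / "reads.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimulatedReads(sam_path, truth_path, truth)


@dataclass
class ExpressionModel:
    """NB expression with planted DE genes, enriched sets, and compositions."""

    n_cells_per_group: int = 200
    groups: tuple[str, ...] = ("AGLCD", "HD")
    n_genes: int = 2000
    n_de: int = 50
    lfc: float = 2.0  # planted log2 fold-change, up in the first group
    base_mean_log_mu: float = -0.5
    base_mean_log_sigma: float = 1.0
    dispersion: float = 0.5
    # high-expression housekeeping background that dominates library size
    # (stands in for the untested bulk of the transcriptome, so planting DE
    # in the test genes barely perturbs per-cell totals / composition —
    # the background must carry ~50x the test-gene mass for the residual
    # shift to stay well below per-cell library-size noise)
    n_filler: int = 200
    filler_mean: float = 500.0
    n_sets: int = 10
    set_size: int = 30
    n_enriched_sets: int = 3
    cell_types: tuple[str, ...] = ("CD8 TEM", "CD8 TCM", "CD4 TCM", "MAIT", "Treg")
    dirichlet_conc: float = 50.0
    tissue: str = "blood"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


@dataclass
class SimulatedExpression:
    mtx_path: Path
    barcodes_path: Path
    features_path: Path
    annotation_path: Path
    gmt_path: Path
    de_truth: pd.DataFrame
    set_truth: pd.DataFrame


def simulate_expression(model: ExpressionModel, out_dir: str | Path) -> SimulatedExpression:
    """Simulate a cell-by-gene NB count matrix with planted structure.

    DE genes (chosen among reasonably expressed genes) are upregulated by
    2^lfc in the first group; enriched gene sets are drawn from the planted
    DE genes, null sets from the remainder; per-sample cell-type
    compositions follow a Dirichlet-multinomial.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(model.seed)
    genes = np.concatenate(
        [
            np.array([f"G{i:05d}" for i in range(model.n_genes)]),
            np.array([f"HK{i:04d}" for i in range(model.n_filler)]),
        ]
    )
    base_mean = np.concatenate(
        [
            rng.lognormal(model.base_mean_log_mu, model.base_mean_log_sigma, model.n_genes),
            np.full(model.n_filler, model.filler_mean),
        ]
    )
    n_total = model.n_genes + model.n_filler

    expressed = np.flatnonzero(base_mean[: model.n_genes] >= 0.5)
    if model.n_de > len(expressed):
        raise ValueError("not enough adequately expressed genes to plant DE")
    de_idx = rng.choice(expressed, size=model.n_de, replace=False)
    de_mask = np.zeros(n_total, bool)
    de_mask[de_idx] = True

    size = 1.0 / model.dispersion
    counts_blocks, barcodes, ann_rows = [], [], []
    base_type_props = rng.dirichlet(np.full(len(model.cell_types), 5.0))
    for gi, group in enumerate(model.groups):
        mean = base_mean.copy()
        if gi == 0:
            mean[de_mask] *= 2.0**model.lfc
        p = size / (size + mean)
        block = rng.negative_binomial(size, p, size=(model.n_cells_per_group, n_total))
        counts_blocks.append(block)
        sample_id = f"{group}_s1"
        type_p = rng.dirichlet(model.dirichlet_conc * base_type_props)
        types = rng.choice(model.cell_types, size=model.n_cells_per_group, p=type_p)
        for ci in range(model.n_cells_per_group):
            bc = f"{group}BC{ci:06d}"
            barcodes.append(bc)
            ann_rows.append(
                {
                    "cell_barcode": bc,
                    "sample_id": sample_id,
                    "tissue": model.tissue,
                    "cell_type": types[ci],
                    "group": group,
                }
            )
    counts = pd.DataFrame(np.vstack(counts_blocks), index=barcodes, columns=genes)

    mtx = out_dir / "matrix.mtx"
    bar = out_dir / "barcodes.tsv"
    feat = out_dir / "features.tsv"
    io_formats.write_counts_mtx(counts, mtx, bar, feat)
    ann_path = out_dir / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(ann_path, sep="\t", index=False)

    de_genes = genes[de_mask]
    non_de = genes[: model.n_genes][~de_mask[: model.n_genes]]
    sets: dict[str, set[str]] = {}
    set_rows = []
    for si in range(model.n_sets):
        enriched = si < model.n_enriched_sets
        if enriched:
            take = min(model.set_size, len(de_genes))
            members = set(rng.choice(de_genes, size=take, replace=False))
        else:
            members = set(rng.choice(non_de, size=model.set_size, replace=False))
        name = f"SET_{'UP' if enriched else 'NULL'}_{si:02d}"
        sets[name] = members
        set_rows.append({"set": name, "enriched": enriched, "size": len(members)})
    gmt_path = out_dir / "sets.gmt"
    io_formats.write_gmt(sets, gmt_path)

    de_truth = pd.DataFrame({"gene": genes, "is_de": de_mask, "lfc": np.where(de_mask, model.lfc, 0.0)})
    de_truth.to_csv(out_dir / "de.truth.tsv", sep="\t", index=False)
    set_truth = pd.DataFrame(set_rows)
    set_truth.to_csv(out_dir / "sets.truth.tsv", sep="\t", index=False)
    return SimulatedExpression(mtx, bar, feat, ann_path, gmt_path, de_truth, set_truth)
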