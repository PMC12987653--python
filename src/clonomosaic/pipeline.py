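"""End-to-end orchestration: simulate -> clonality -> sharing -> mosaicism ->
contrasts, with a manifest for reproducibility.

Stages communicate exclusively through TSV files in the run directory; the
manifest records the config hash, seeds, per-stage row counts and output
checksums, so two runs of the same config can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clonality, differential, io_formats, mosaicism, sharing, synthetic

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with the full list of config schema violations."""


DEFAULT_CONFIG = {
    "seed": 0,
    "clonality": {
        "scheme": "paired",
        "depth": "auto",
        "n_boot": 1000,
        "ci": 0.95,
        "dominant_prop": 0.01,
        "dominant_n": 50,
    },
    "sharing": {"pseudocount": 0.5, "scope": "union"},
    "mosaicism": {"alt_min": 1},
    "differential": {"min_frac": 0.1, "n_perm": 1000, "min_set_size": 5, "scale": 1e4},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _merged(config: dict) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key].update(value)
        else:
            out[key] = value
    return out


def validate_config(config: dict) -> list[str]:
    """Schema check; returns ALL failures, not just the first."""
    cfg = _merged(config)
    failures = []
    if not isinstance(cfg.get("seed"), int):
        failures.append("seed must be an integer")
    clon = cfg["clonality"]
    if clon["scheme"] not in ("paired", "beta"):
        failures.append(f"clonality.scheme must be paired|beta, got {clon['scheme']!r}")
    if not (isinstance(clon["n_boot"], int) and clon["n_boot"] >= 1):
        failures.append("clonality.n_boot must be a positive integer")
    if not (0 < clon["ci"] < 1):
        failures.append("clonality.ci must be in (0, 1)")
    if clon["depth"] != "auto" and not (isinstance(clon["depth"], int) and clon["depth"] >= 1):
        failures.append("clonality.depth must be 'auto' or a positive integer")
    if cfg["sharing"]["scope"] not in ("union", "shared"):
        failures.append("sharing.scope must be union|shared")
    if cfg["sharing"]["pseudocount"] <= 0:
        failures.append("sharing.pseudocount must be > 0")
    if not (isinstance(cfg["mosaicism"]["alt_min"], int) and cfg["mosaicism"]["alt_min"] >= 1):
        failures.append("mosaicism.alt_min must be a positive integer")
    locus = cfg["mosaicism"].get("locus")
    if locus is not None:
        try:
            io_formats.VariantLocus.from_string(locus)
        except (ValueError, io_formats.FormatError) as exc:
            failures.append(f"mosaicism.locus: {exc}")
    if not (0 <= cfg["differential"]["min_frac"] < 1):
        failures.append("differential.min_frac must be in [0, 1)")
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if not has_sim and not has_inputs:
        failures.append("config must provide a 'simulate' or an 'inputs' section")
    return failures


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run(config: dict, out_dir: str | Path) -> Path:
    """Execute the configured stages into ``out_dir``; returns the run dir."""
    failures = validate_config(config)
    if failures:
        raise ConfigError("invalid config:\n" + "\n".join(f"- {f}" for f in failures))
    cfg = _merged(config)
    seed = cfg["seed"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stages": {},
    }
    # --- stage 0: inputs (simulated or provided) --------------------------
    inputs = dict(cfg.get("inputs") or {})
    if "simulate" in cfg:
        sim = cfg["simulate"]
        sim_dir = out / "inputs"
        stage: dict = {"status": "completed", "outputs": {}}
        if "repertoires" in sim:
            airr_paths = []
            for i, spec in enumerate(sim["repertoires"]):
                spec = dict(spec)
                sample_id = spec.pop("sample_id", f"sample{i}")
                model = synthetic.RepertoireModel(seed=seed + 100 + i, **spec)
                res = synthetic.simulate_repertoire(model, sim_dir, sample_id=sample_id)
                airr_paths.append(str(res.airr_path))
            inputs["airr"] = airr_paths
        if "reads" in sim:
            model = synthetic.ReadModel(seed=seed + 200, **sim["reads"])
            res = synthetic.simulate_reads(model, sim_dir)
            inputs["sam"] = str(res.sam_path)
            cfg["mosaicism"].setdefault(
                "locus",
                f"{model.locus.contig}:{model.locus.position}:{model.locus.ref_allele}:{model.locus.alt_allele}",
            )
            # annotations for the read cells so mosaicism can be summarized
            rng = np.random.default_rng(seed + 201)
            types = ("CD8 TEM", "CD8 TCM", "CD4 TCM", "MAIT")
            ann = pd.DataFrame(
                {
                    "cell_barcode": res.truth["cell_barcode"],
                    "sample_id": "patient_blood",
                    "tissue": "blood",
                    "cell_type": rng.choice(types, size=len(res.truth)),
                    "group": "patient",
                }
            )
            ann_path = sim_dir / "reads.annotations.tsv"
            ann.to_csv(ann_path, sep="\t", index=False)
            inputs["variant_annotations"] = str(ann_path)
        if "expression" in sim:
            model = synthetic.ExpressionModel(seed=seed + 300, **sim["expression"])
            res = synthetic.simulate_expression(model, sim_dir)
            inputs.update(
                mtx=str(res.mtx_path),
                barcodes=str(res.barcodes_path),
                features=str(res.features_path),
                annotations=str(res.annotation_path),
                gmt=str(res.gmt_path),
            )
        stage["outputs"] = {p.name: _sha256(p) for p in sorted(sim_dir.glob("*")) if p.is_file()}
        manifest["stages"]["simulate"] = stage

    # --- stage 1: clonality ----------------------------------------------
    reps = []
    if inputs.get("airr"):
        clon = cfg["clonality"]
        for path in inputs["airr"]:
            records = io_formats.read_airr(path)
            sample_id = Path(path).name.replace(".airr.tsv", "")
            reps.append(
                clonality.build_repertoire(records, sample_id=sample_id, scheme=clon["scheme"])
            )
        depth = clonality.common_depth(reps) if clon["depth"] == "auto" else clon["depth"]
        div = clonality.diversity_table(
            reps, depth=depth, n_boot=clon["n_boot"], ci=clon["ci"], seed=seed
        )
        occ_rows = []
        for rep in reps:
            for (lo, hi), val in clonality.occupancy_profile(rep).items():
                occ_rows.append({"sample": rep.sample_id, "bin_low": lo, "bin_high": hi, "value": val})
        class_rows = []
        cell_rows = []
        for rep in reps:
            classes = clonality.classify_clones(
                rep, dominant_prop=clon["dominant_prop"], dominant_n=clon["dominant_n"]
            )
            for c in classes:
                class_rows.append(
                    {
                        "sample": rep.sample_id,
                        "cdr3_nt_trb": c.key.cdr3_nt_trb,
                        "cdr3_nt_tra": c.key.cdr3_nt_tra,
                        "n_c": c.n_c,
                        "proportion": c.proportion,
                        "clone_class": c.clone_class,
                        "dominant": c.dominant,
                    }
                )
            cell_rows.append(clonality.cell_class_table(rep, classes))
        cdir = out / "clonality"
        n1 = _write(div, cdir / "diversity.tsv")
        n2 = _write(pd.DataFrame(occ_rows), cdir / "occupancy.tsv")
        n3 = _write(pd.DataFrame(class_rows), cdir / "clone_classes.tsv")
        n4 = _write(pd.concat(cell_rows, ignore_index=True), cdir / "cell_classes.tsv")
        manifest["stages"]["clonality"] = {
            "status": "completed",
            "rows": {"diversity": n1, "occupancy": n2, "clone_classes": n3, "cell_classes": n4},
            "outputs": {p.name: _sha256(p) for p in sorted(cdir.glob("*.tsv"))},
        }
    else:
        manifest["stages"]["clonality"] = {"status": "skipped", "reason": "no AIRR inputs"}

    # --- stage 2: sharing --------------------------------------------------
    if len(reps) >= 2:
        sh = cfg["sharing"]
        scmap = sharing.join_repertoires(reps)
        shared_tbl = sharing.shared_clone_table(scmap)
        upset = sharing.upset_counts(scmap)
        upset_tbl = pd.DataFrame(
            [{"pattern": "+".join(k), "count": v} for k, v in sorted(upset.items())]
        )
        conc_rows = []
        samples = scmap.samples
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                c = sharing.concordance(
                    scmap, samples[i], samples[j],
                    pseudocount=sh["pseudocount"], scope=sh["scope"],
                )
                conc_rows.append(c.__dict__ | {"flags": ",".join(c.flags)})
        sdir = out / "sharing"
        n1 = _write(shared_tbl, sdir / "shared_clones.tsv")
        n2 = _write(upset_tbl, sdir / "upset.tsv")
        n3 = _write(pd.DataFrame(conc_rows), sdir / "concordance.tsv")
        manifest["stages"]["sharing"] = {
            "status": "completed",
            "rows": {"shared_clones": n1, "upset": n2, "concordance": n3},
            "outputs": {p.name: _sha256(p) for p in sorted(sdir.glob("*.tsv"))},
        }
    else:
        manifest["stages"]["sharing"] = {"status": "skipped", "reason": "fewer than two repertoires"}

    # --- stage 3: mosaicism -------------------------------------------------
    locus_spec = cfg["mosaicism"].get("locus")
    if inputs.get("sam") and locus_spec:
        locus = io_formats.VariantLocus.from_string(locus_spec)
        stream = io_formats.read_tagged_alignments(inputs["sam"], locus)
        counts = mosaicism.collapse_umis(stream)
        calls = mosaicism.call_cells(counts, locus, alt_min=cfg["mosaicism"]["alt_min"])
        mdir = out / "mosaicism"
        n1 = _write(mosaicism.calls_table(calls), mdir / "cell_calls.tsv")
        rows = {"cell_calls": n1}
        ann_path = inputs.get("variant_annotations") or inputs.get("annotations")
        if ann_path:
            ann = io_formats.read_annotations(ann_path)
            summary = mosaicism.summarize_mosaicism(calls, ann)
            rows["summary"] = _write(summary, mdir / "summary.tsv")
        manifest["stages"]["mosaicism"] = {
            "status": "completed",
            "rows": rows,
            "outputs": {p.name: _sha256(p) for p in sorted(mdir.glob("*.tsv"))},
        }
    else:
        reason = "no SAM input" if not inputs.get("sam") else "no locus configured"
        manifest["stages"]["mosaicism"] = {"status": "skipped", "reason": reason}

    # --- stage 4: contrasts --------------------------------------------------
    if inputs.get("mtx"):
        diff = cfg["differential"]
        raw = io_formats.read_counts_mtx(inputs["mtx"], inputs["barcodes"], inputs["features"])
        ann = io_formats.read_annotations(inputs["annotations"])
        expr = differential.normalize_counts(raw, scale=diff["scale"])
        groups = list(dict.fromkeys(ann["group"]))
        if len(groups) < 2:
            manifest["stages"]["contrasts"] = {"status": "skipped", "reason": "fewer than two groups"}
        else:
            ga = tuple(ann.loc[ann["group"] == groups[0], "cell_barcode"])
            gb = tuple(ann.loc[ann["group"] == groups[1], "cell_barcode"])
            tissue = ann["tissue"].iloc[0]
            spec = differential.ContrastSpec(ga, gb, tissue, f"{groups[0]}_vs_{groups[1]}")
            dge_res = differential.dge(spec, expr, min_frac=diff["min_frac"])
            ddir = out / "differential"
            rows = {"dge": _write(dge_res.table, ddir / f"dge_{spec.label}.tsv")}
            if inputs.get("gmt"):
                sets = io_formats.read_gene_sets(inputs["gmt"], min_size=diff["min_set_size"])
                tbl = dge_res.table
                score = np.sign(tbl["lfc"]) * (-np.log10(np.clip(tbl["p"], 1e-300, None)))
                ranking = pd.Series(score.to_numpy(), index=tbl["gene"].to_numpy())
                enr = differential.gsea_preranked(
                    ranking, sets, n_perm=diff["n_perm"],
                    min_size=diff["min_set_size"], seed=seed,
                )
                rows["gsea"] = _write(
                    differential.enrichment_table(enr), ddir / f"gsea_{spec.label}.tsv"
                )
            props = differential.proportion_forest(ann, reference_group=groups[-1])
            rows["proportions"] = _write(
                differential.proportion_table(props), ddir / "proportions.tsv"
            )
            manifest["stages"]["contrasts"] = {
                "status": "completed",
                "rows": rows,
                "outputs": {p.name: _sha256(p) for p in sorted(ddir.glob("*.tsv"))},
            }
    else:
        manifest["stages"]["contrasts"] = {"status": "skipped", "reason": "no expression inputs"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


# --- report ---------------------------------------------------------------


def report(run_dir: str | Path, out_dir: str | Path | None = None) -> list[str]:
    """Render summary panels from the run's TSVs only.

    Returns the list of panel files written; missing stage outputs cause
    the corresponding panel to be omitted with a note in report_notes.txt.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir else run_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    panels: list[str] = []
    notes: list[str] = []

    def _panel(name: str, fn) -> None:
        try:
            fig = fn()
        except FileNotFoundError as exc:
            notes.append(f"{name}: omitted ({exc})")
            return
        path = out / f"{name}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        panels.append(path.name)

    def _occupancy():
        df = pd.read_csv(run_dir / "clonality" / "occupancy.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        bottom = {}
        for (lo, hi), grp in df.groupby(["bin_low", "bin_high"]):
            xs = grp["sample"].tolist()
            ys = grp["value"].to_numpy()
            b = [bottom.get(x, 0.0) for x in xs]
            ax.bar(xs, ys, bottom=b, label=f"({lo:g}, {hi:g}]")
            for x, y, b0 in zip(xs, ys, b):
                bottom[x] = b0 + y
        ax.set_ylabel("repertoire occupancy")
        ax.legend(fontsize=6)
        ax.tick_params(axis="x", rotation=45)
        return fig

    def _diversity():
        df = pd.read_csv(run_dir / "clonality" / "diversity.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3))
        y = np.arange(len(df))
        pt = df["point"].to_numpy()
        ax.errorbar(
            pt, y,
            xerr=[pt - df["ci_low"].to_numpy(), df["ci_high"].to_numpy() - pt],
            fmt="o", capsize=3,
        )
        ax.set_yticks(y, df["sample"].tolist())
        ax.set_xlabel(f"inverse Simpson (depth {df['depth'].iloc[0]})")
        return fig

    def _upset():
        df = pd.read_csv(run_dir / "sharing" / "upset.tsv", sep="\t")
        if df.empty:
            raise FileNotFoundError("empty upset table")
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(df["pattern"].tolist(), df["count"].to_numpy())
        ax.set_ylabel("clonotypes")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        return fig

    def _concordance():
        conc = pd.read_csv(run_dir / "sharing" / "concordance.tsv", sep="\t")
        shared = pd.read_csv(run_dir / "sharing" / "shared_clones.tsv", sep="\t")
        row = conc.iloc[0]
        a, b = row["sample_a"], row["sample_b"]
        na = shared[a].sum()
        nb = shared[b].sum()
        qa, qb = row["pseudocount"] / na, row["pseudocount"] / nb
        x = np.log10(np.where(shared[a] > 0, shared[a] / na, qa))
        y = np.log10(np.where(shared[b] > 0, shared[b] / nb, qb))
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(x, y, s=6, alpha=0.5)
        if np.isfinite(row["slope"]):
            xs = np.linspace(x.min(), x.max(), 10)
            ax.plot(xs, row["slope"] * xs + row["intercept"], "k--")
        ax.set_xlabel(f"log10 proportion {a}")
        ax.set_ylabel(f"log10 proportion {b}")
        ax.set_title(f"R^2 = {row['r_squared']:.2f}")
        return fig

    def _mosaic():
        df = pd.read_csv(run_dir / "mosaicism" / "summary.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3))
        labels = df["sample_id"] + " / " + df["cell_type"]
        ax.bar(labels.tolist(), df["mutant_fraction"].to_numpy())
        ax.set_ylabel("mutant fraction (covered cells)")
        ax.tick_params(axis="x", rotation=45, labelsize=6)
        return fig

    def _volcano():
        paths = sorted((run_dir / "differential").glob("dge_*.tsv"))
        if not paths:
            raise FileNotFoundError("no DGE tables")
        df = pd.read_csv(paths[0], sep="\t")
        fig, ax = plt.subplots(figsize=(4, 4))
        sig = df["q"] < 0.05
        ax.scatter(df["lfc"], -np.log10(np.clip(df["p"], 1e-300, None)), s=4,
                   c=np.where(sig, "crimson", "grey"))
        ax.set_xlabel("log2 fold-change")
        ax.set_ylabel("-log10 p")
        return fig

    def _enrichment():
        paths = sorted((run_dir / "differential").glob("gsea_*.tsv"))
        if not paths:
            raise FileNotFoundError("no GSEA tables")
        df = pd.read_csv(paths[0], sep="\t").sort_values("nes")
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.hlines(df["set"], 0, df["nes"], color="grey")
        ax.plot(df["nes"], df["set"], "o")
        ax.set_xlabel("NES")
        ax.tick_params(labelsize=6)
        return fig

    def _proportions():
        df = pd.read_csv(run_dir / "differential" / "proportions.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3))
        y = np.arange(len(df))
        d = df["delta"].to_numpy()
        ax.errorbar(d, y,
                    xerr=[d - df["ci_low"].to_numpy(), df["ci_high"].to_numpy() - d],
                    fmt="o", capsize=3)
        ax.axvline(0, color="grey", ls=":")
        ax.set_yticks(y, (df["cell_type"] + " (" + df["group"] + ")").tolist())
        ax.set_xlabel("delta arcsin-sqrt proportion")
        ax.tick_params(labelsize=6)
        return fig

    for name, fn in [
        ("occupancy", _occupancy), ("diversity", _diversity), ("upset", _upset),
        ("concordance", _concordance), ("mosaicism", _mosaic), ("volcano", _volcano),
        ("enrichment", _enrichment), ("proportions", _proportions),
    ]:
        _panel(name, fn)

    (out / "report_notes.txt").write_text(
        "panels: " + ", ".join(panels) + "\n" + "\n".join(notes) + "\n"
    )
    return panels
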