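"""End-to-end orchestration: simulate/load -> QC/call -> screen -> SAM ->
cluster -> signature -> report, with a run manifest.

A run is driven by a single config mapping (YAML on disk). Outputs land in
a run directory; inputs are never mutated. The manifest records the config
snapshot, seeds, parameter values, stage-by-stage filter counts (the
"screen funnel") and a SHA-256 digest of every output file, so a rerun
with the same seeds is checkable byte-for-byte on deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calling, cluster, io, sam, simulate
from .vocab import LYMPHOID_CLASSES, SAMPLE_CLASSES

log = logging.getLogger("cghsig")


class PipelineError(RuntimeError):
    pass


DEFAULT_CONFIG = {
    "simulate": {"preset": "demo", "seed": 17},
    "calling": {"k": 4.0, "min_adjacent": 2, "min_samples": 3,
                "drop_sex": True},
    "sam": {"class_a": ["BCL", "BCmix"],
            "class_b": ["CP", "AP", "BCM", "control"],
            "n_permutations": 1000, "seed": 17, "k_top": 22,
            "false_stat": "mean"},
    "signature": {"k": 3.0, "min_fraction": 0.5,
                  "target_class": ["BCL", "BCmix"]},
}


def load_config(path_or_mapping) -> dict:
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_mapping or {})
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values or {})
    return cfg


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    parameters: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # filename -> sha256

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[Path(path).name] = digest

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=2, sort_keys=True) + "\n")


def _preflight(cfg: dict) -> None:
    """Validate the config before any work; list every problem at once."""
    problems: list[str] = []
    sim = cfg.get("simulate", {})
    inputs = sim.get("inputs")
    if inputs:
        for key in ("probes", "fr", "samples"):
            p = inputs.get(key)
            if p is None:
                problems.append(f"simulate.inputs.{key} missing")
            elif not Path(p).exists():
                problems.append(f"input file not found: {p}")
    elif sim.get("preset", "demo") not in ("demo", "full", "null"):
        problems.append(f"unknown preset {sim.get('preset')!r}")
    for side in ("class_a", "class_b"):
        bad = set(cfg["sam"].get(side, ())) - set(SAMPLE_CLASSES)
        if bad:
            problems.append(f"sam.{side}: unknown classes {sorted(bad)}")
    if set(cfg["sam"]["class_a"]) & set(cfg["sam"]["class_b"]):
        problems.append("sam class_a and class_b overlap")
    if problems:
        raise PipelineError("pre-flight failed: " + "; ".join(problems))


def _acquire(cfg: dict):
    """Stage 0: simulate a cohort or load one from disk."""
    sim = cfg["simulate"]
    if sim.get("inputs"):
        inputs = sim["inputs"]
        grid = io.read_probe_table(inputs["probes"])
        fr = io.read_fr_matrix(inputs["fr"], grid)
        samples = io.read_sample_sheet(inputs["samples"])
        mask = (io.load_cnv_mask(inputs["cnv_mask"])
                if inputs.get("cnv_mask") else io.CNVMask.from_intervals([]))
        return grid, fr, samples, mask, None
    preset = {"demo": simulate.demo_config, "full": simulate.full_config,
              "null": simulate.null_config}[sim.get("preset", "demo")]
    overrides = {k: v for k, v in sim.items()
                 if k not in ("preset", "seed", "inputs")}
    cohort = simulate.simulate_cohort(preset(seed=int(sim.get("seed", 0)),
                                             **overrides))
    mask = io.CNVMask(intervals=cohort.cnv_mask, merged=True)
    return cohort.grid, cohort.fr, cohort.samples, mask, cohort


def run_pipeline(config, outdir) -> RunManifest:
    """Execute the full analysis; write all artifacts under ``outdir``.

    Stages: acquire (simulate or load) -> sex-chromosome drop -> robust QC
    and +-k*SD calling -> adjacency/recurrence screen -> CNV masking ->
    two-class SAM -> top-gap selection -> hierarchical clustering ->
    region signature calls -> cohort summary. Any stage failure aborts
    with the stage name; a partial manifest is still written.
    """
    cfg = load_config(config)
    _preflight(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    stage = "acquire"
    try:
        grid, fr, samples, mask, cohort = _acquire(cfg)
        if cohort is not None:
            io.write_probe_table(grid, outdir / "probes.bed")
            io.write_fr_matrix(fr, outdir / "fr_matrix.tsv")
            io.write_sample_sheet(samples, outdir / "samples.tsv")
            io.write_cnv_mask(cohort.cnv_mask, outdir / "cnv_mask.bed")
            io.write_truth(cohort.truth, outdir / "truth.tsv")
        manifest.counts["n_probes_input"] = len(grid)
        manifest.counts["n_samples"] = len(samples)

        stage = "drop_sex"
        ccfg = cfg["calling"]
        if ccfg.get("drop_sex", True):
            fr, grid = calling.drop_sex_chromosomes(fr, grid)
        manifest.counts["n_probes_autosomal"] = len(grid)

        stage = "qc_calling"
        qc = calling.sample_qc(fr)
        qc.to_csv(outdir / "sample_qc.tsv", sep="\t",
                  float_format=io.FLOAT_FMT)
        k = float(ccfg.get("k", 4.0))
        calls = calling.call_matrix(fr.to_numpy(), qc["center"],
                                    qc["robust_sd"], k=k)
        io.write_calls(pd.DataFrame(calls, index=fr.index,
                                    columns=fr.columns),
                       outdir / "calls.tsv")
        manifest.parameters["call_k"] = k
        manifest.counts["n_calls"] = int((calls != 0).sum())

        stage = "recurrence_screen"
        loci = calling.recurrent_adjacent_loci(
            calls, grid, min_adjacent=int(ccfg.get("min_adjacent", 2)),
            min_samples=int(ccfg.get("min_samples", 3)),
            sample_ids=fr.columns, k=k)
        manifest.counts["n_loci_screen"] = len(loci)
        stage = "cnv_mask"
        kept = calling.apply_cnv_mask(loci, mask, grid)
        manifest.counts["n_loci_after_cnv_mask"] = len(kept)
        kept.to_frame().to_csv(outdir / "recurrent_loci.tsv", sep="\t",
                               index=False)

        stage = "sam"
        scfg = cfg["sam"]
        class_a, class_b = set(scfg["class_a"]), set(scfg["class_b"])
        in_a = samples["class"].isin(class_a)
        in_b = samples["class"].isin(class_b)
        if in_a.sum() < 2 or in_b.sum() < 2:
            raise PipelineError("two-class analysis needs >= 2 samples per "
                                "class in the sample sheet")
        use = (in_a | in_b).to_numpy()
        ids = samples.loc[use, "sample_id"]
        y = np.where(in_a[use], "lymphoid", "other")
        X = fr.loc[:, ids].to_numpy().T
        model = sam.SAMTwoClass(
            n_permutations=int(scfg.get("n_permutations", 1000)),
            random_state=int(scfg.get("seed", 0)),
            false_stat=scfg.get("false_stat", "mean"))
        model.fit(X, y)
        manifest.parameters.update(
            s0=model.s0_, n_arrangements=model.n_arrangements_,
            exhaustive=model.exhaustive_,
            sam_classes={"a": sorted(class_a), "b": sorted(class_b)},
            sam_n_samples=int(use.sum()))
        model.results_frame(probe_ids=fr.index).to_csv(
            outdir / "sam_results.tsv", sep="\t", index=False,
            float_format=io.FLOAT_FMT)
        model.delta_table_.to_csv(outdir / "delta_table.tsv", sep="\t",
                                  index=False, float_format=io.FLOAT_FMT)
        manifest.counts["n_fdr0"] = int(model.significant_fdr0_.size)
        k_top = int(scfg.get("k_top", 22))
        top = model.top_by_delta_gap(k_top)
        pd.DataFrame({"probe_id": fr.index[top],
                      "address": [grid.address(i) for i in top],
                      "gene": grid.df["gene"].iloc[top].fillna(".").values,
                      "d": model.d_[top], "gap": model.gap_[top]}
                     ).to_csv(outdir / "top_probes.tsv", sep="\t",
                              index=False, float_format=io.FLOAT_FMT)

        stage = "cluster"
        fr_sel = fr.loc[:, ids].iloc[top]
        order, Z = cluster.hierarchical_cluster(fr_sel)
        io.save_newick(Z, list(fr_sel.columns), outdir / "dendrogram.nwk")
        fr_sel.loc[:, order].to_csv(outdir / "heatmap_matrix.tsv", sep="\t",
                                    float_format=io.FLOAT_FMT)

        stage = "signature"
        gcfg = cfg["signature"]
        if gcfg.get("regions"):
            regions = cluster.read_regions(gcfg["regions"])
        elif cohort is not None:
            regions = cluster.regions_from_templates(
                _templates_from_cohort(cohort))
        else:
            raise PipelineError("signature stage needs a regions file when "
                                "running on loaded data")
        k_sig = float(gcfg.get("k", 3.0))
        sig_calls = calling.call_matrix(fr.to_numpy(), qc["center"],
                                        qc["robust_sd"], k=k_sig)
        flags = cluster.signature_flags(
            sig_calls, grid, regions, fr.columns,
            min_fraction=float(gcfg.get("min_fraction", 0.5)),
            missing=fr.isna().to_numpy())
        flags["concomitant_7p9p"] = cluster.classify_concomitant(flags,
                                                                 regions)
        flags.to_csv(outdir / "signature_flags.tsv", sep="\t")
        summary = cluster.cohort_summary(
            flags.drop(columns="concomitant_7p9p"), samples,
            gcfg.get("target_class", sorted(LYMPHOID_CLASSES)))
        summary.to_csv(outdir / "signature_summary.tsv", sep="\t",
                       index=False, float_format=io.FLOAT_FMT)
        manifest.counts["n_concomitant"] = int(
            flags["concomitant_7p9p"].sum())
    except Exception as exc:
        manifest.counts["failed_stage"] = stage
        manifest.write(outdir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest.add_output(p)
    manifest.write(outdir / "manifest.json")
    return manifest


def _templates_from_cohort(cohort) -> list:
    """Recover unique signature region templates from a cohort truth set."""
    seen = {}
    for ev in cohort.truth.events:
        if ev.kind == "signature" and ev.name not in seen:
            seen[ev.name] = simulate.SignatureTemplate(
                ev.name, ev.chrom, ev.start, ev.end, ev.role,
                copy_change=ev.copy_change)
    return list(seen.values())


def paired_reference_mode(fr_bc, fr_cp) -> pd.Series:
    """Re-reference a blast-crisis profile against its chronic-phase pair.

    Both columns must share the probe grid. The derived per-probe ratio
    ``fr_bc / fr_cp`` emulates hybridising BC against CP DNA: aberrations
    shared by both phases cancel toward 1, while BC-specific losses stay
    below 1. A CP-only aberration shows up as the reciprocal artefact
    (e.g. a CP-only 0.5 loss yields ~2). Zero CP ratios give missing
    values (logged); missing propagates.
    """
    bc = pd.Series(fr_bc).astype(float)
    cp = pd.Series(fr_cp).astype(float)
    if not bc.index.equals(cp.index):
        raise PipelineError("paired columns are not on the same probe grid")
    zero = (cp == 0) & cp.notna()
    if zero.any():
        log.info("paired reference: %d probes with zero CP ratio set "
                 "missing", int(zero.sum()))
    out = bc / cp.where(~zero)
    out.name = "bc_vs_cp"
    return out
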