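"""End-to-end pipeline: simulate -> map/filter -> markers -> linkage -> bin
-> stats (plus optional stoichiometry and probe stages), driven by one YAML
configuration, with a run manifest recording parameters and output
checksums for every stage."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from . import binning, bin_stats, coverage_profiling as cov, linkage_graph, marker_genes
from . import probe_match, stoichiometry, synthetic_data
from .alignments import write_sam

logger = logging.getLogger(__name__)

__all__ = ["StageError", "load_config", "validate_config", "run"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    cfg.setdefault("seed", 0)
    return cfg


_FILE_KEYS = ("cycle_csv", "probe_tsv", "sequences_fasta", "taxonomy_tsv", "marker_table")


def validate_config(cfg: dict) -> None:
    """Check referenced input files exist before any stage runs."""
    missing = []
    for section in cfg.values():
        if not isinstance(section, dict):
            continue
        for key in _FILE_KEYS:
            path = section.get(key)
            if path and not Path(path).exists():
                missing.append(str(path))
    if missing:
        raise FileNotFoundError(f"configured input files not found: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(cfg: dict, outdir: str | Path) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``manifest.json``): per stage the
    parameters used, record counts in/out of every filter, and a sha256
    checksum of every output file.  Rerunning with identical config is
    byte-identical for all deterministic stages.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict[str, Any] = {"seed": seed, "config": cfg, "stages": {}}
    state: dict[str, Any] = {}

    def record_stage(name: str, params: dict, outputs: list[Path], counts: dict | None = None):
        manifest["stages"][name] = {
            "params": params,
            "outputs": {p.name: _sha256(p) for p in outputs},
            **({"counts": counts} if counts else {}),
        }

    def guarded(name: str, fn: Callable[[], None]) -> None:
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - named stage failure contract
            manifest["failed_stage"] = {"stage": name, "cause": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise StageError(name, exc) from exc

    # -- community ----------------------------------------------------------
    def stage_community() -> None:
        ccfg = dict(cfg.get("community", {}))
        if not ccfg:
            spec = synthetic_data.default_community_spec(seed)
            mean_depth = synthetic_data.DEFAULT_MEAN_DEPTH
        else:
            depths = ccfg.pop("depth_design", None)
            mean_depth = ccfg.pop("mean_depth", 20.0)
            if depths is not None:
                ab, mean_depth = synthetic_data.abundance_from_depths(np.asarray(depths))
                ccfg["abundance_matrix"] = ab
                ccfg["n_genomes"] = ab.shape[0]
            spec = synthetic_data.CommunitySpec(seed=seed, **ccfg)
        truth = synthetic_data.generate_community(spec)
        paths = synthetic_data.write_community(truth, outdir)
        state.update(spec=spec, truth=truth, mean_depth=mean_depth)
        record_stage(
            "community",
            {"n_genomes": spec.n_genomes, "n_markers": spec.n_markers, "seed": seed},
            list(paths.values()),
            {"scaffolds": len(truth.scaffold_sequences)},
        )

    # -- reads ---------------------------------------------------------------
    def stage_reads() -> None:
        rcfg = cfg.get("reads", {})
        spec, truth = state["spec"], state["truth"]
        per_sample = synthetic_data.simulate_alignments(
            truth,
            spec,
            mean_depth=float(rcfg.get("mean_depth", state["mean_depth"])),
            read_bp=int(rcfg.get("read_bp", 150)),
            insert_bp=int(rcfg.get("insert_bp", 300)),
            count_model=str(rcfg.get("count_model", "poisson")),
        )
        lengths = {s: len(seq) for s, seq in truth.scaffold_sequences.items()}
        outputs, counts = [], {}
        for sample, records in per_sample.items():
            path = outdir / f"{sample}.sam"
            write_sam(records, lengths, path)
            outputs.append(path)
            counts[sample] = len(records)
        state["alignments"] = per_sample
        record_stage("reads", dict(rcfg), outputs, counts)

    # -- coverage ------------------------------------------------------------
    def stage_coverage() -> None:
        fcfg = cfg.get("filter", {})
        params = cov.AlignmentFilterParams(
            min_identity=float(fcfg.get("min_identity", 0.95)),
            min_aligned_fraction=float(fcfg.get("min_aligned_fraction", 0.70)),
        )
        truth = state["truth"]
        profiles: dict[str, cov.CoverageProfile] = {}
        filtered: dict[str, list] = {}
        counts = {}
        for sample, records in state["alignments"].items():
            kept = cov.filter_alignments(records, params)
            filtered[sample] = kept
            counts[sample] = {"in": len(records), "out": len(kept)}
            profiles = cov.compute_coverage(kept, truth.scaffold_sequences, sample, profiles)
        path = outdir / "coverage.tsv"
        cov.write_coverage_tsv(profiles.values(), path)
        state.update(profiles=profiles, filtered=filtered, filter_params=params)
        record_stage("coverage", {"min_identity": params.min_identity,
                                  "min_aligned_fraction": params.min_aligned_fraction},
                     [path], counts)

    # -- markers -------------------------------------------------------------
    def stage_markers() -> None:
        mcfg = cfg.get("markers", {})
        truth = state["truth"]
        mode = mcfg.get("mode", "signature")
        hits = marker_genes.detect_markers(
            truth.scaffold_sequences,
            truth.catalog,
            mode=mode,
            registry=truth.registry if mode == "signature" else None,
            table=mcfg.get("marker_table"),
        )
        path = outdir / "marker_hits.tsv"
        marker_genes.write_marker_tsv(hits, path)
        state["hits"] = hits
        record_stage("markers", {"mode": mode}, [path], {"hits": len(hits)})

    # -- linkage -------------------------------------------------------------
    def stage_linkage() -> None:
        lcfg = cfg.get("linkage", {})
        min_links = int(lcfg.get("min_links", linkage_graph.DEFAULT_MIN_LINKS))
        pooled = [r for recs in state["filtered"].values() for r in recs]
        edges = linkage_graph.build_linkage(pooled, min_links=min_links)
        path = outdir / "linkage_edges.tsv"
        linkage_graph.write_edges_tsv(edges, path)
        state["edges"] = edges
        record_stage("linkage", {"min_links": min_links}, [path], {"edges": len(edges)})

    # -- bin -----------------------------------------------------------------
    def stage_bin() -> None:
        bcfg = cfg.get("binning", {})
        spec = state["spec"]
        sample_x = bcfg.get("sample_x", spec.sample_ids[0])
        sample_y = bcfg.get("sample_y", spec.sample_ids[1])
        min_bp = int(bcfg.get("min_scaffold_bp", 1000))
        profiles = cov.length_filter(state["profiles"].values(), min_bp=min_bp)
        polygon = bcfg.get("polygon")
        if polygon:
            members = binning.select_by_polygon(
                profiles, sample_x, sample_y, [tuple(v) for v in polygon]
            )
            candidates = [sorted(members)] if members else []
            prov = {"method": "polygon", "polygon": polygon}
        else:
            radius = float(bcfg.get("radius", 0.1))
            min_members = int(bcfg.get("min_members", 2))
            candidates = binning.cluster_coverage(
                profiles, sample_x, sample_y, radius, min_members
            )
            prov = {"method": "cluster", "radius": radius, "min_members": min_members}
        prov["samples"] = [sample_x, sample_y]
        prof_map = state["profiles"]
        bins, reports = [], {}
        for i, cand in enumerate(candidates, 1):
            b, rep = binning.refine_bin(
                cand,
                prof_map,
                state["hits"],
                state["truth"].catalog,
                state["edges"],
                bin_id=f"bin_{i:02d}",
                auto_trim=bool(bcfg.get("auto_trim", False)),
                provenance=prov,
            )
            bins.append(b)
            reports[b.bin_id] = {
                "added": rep.added, "flagged": rep.flagged, "removed": rep.removed,
                "before": rep.before, "after": rep.after,
            }
        bins_path = outdir / "bins.tsv"
        prov_path = outdir / "bin_provenance.json"
        binning.write_bin_tsv(bins, bins_path)
        binning.write_provenance(bins, prov_path)
        (outdir / "refinement_reports.json").write_text(
            json.dumps(reports, indent=2, sort_keys=True)
        )
        state["bins"] = bins
        record_stage("bin", prov, [bins_path, prov_path, outdir / "refinement_reports.json"],
                     {"bins": len(bins)})

    # -- stats ---------------------------------------------------------------
    def stage_stats() -> None:
        truth = state["truth"]
        stats = [
            bin_stats.summarize_bin(
                b.bin_id, b.scaffold_ids, truth.scaffold_sequences,
                state["profiles"], state["hits"], truth.catalog,
                min_n_run=int(cfg.get("stats", {}).get("min_n_run", 10)),
            )
            for b in state["bins"]
        ]
        path = outdir / "bin_stats.tsv"
        bin_stats.stats_frame(stats).to_csv(path, sep="\t", index=False)
        record_stage("stats", dict(cfg.get("stats", {})), [path], {"bins": len(stats)})

    # -- stoichiometry -------------------------------------------------------
    def stage_stoich() -> None:
        scfg = cfg.get("stoichiometry", {})
        if scfg.get("cycle_csv"):
            series = stoichiometry.read_cycle_csv(scfg["cycle_csv"])
        else:
            series = synthetic_data.generate_cycle(
                synthetic_data.CycleSpec(
                    f_pao=float(scfg.get("f_pao", 0.5)),
                    noise_sd_rel=float(scfg.get("noise_sd_rel", 0.0)),
                    seed=seed,
                )
            )
            synthetic_data.write_cycle_csv(series, outdir / "cycle.csv")
        ratios = stoichiometry.transformation_ratios(series)
        est_end = stoichiometry.pao_fraction(ratios, basis="p_vfa")
        est_rate = stoichiometry.pao_fraction(
            stoichiometry.transformation_ratios(series, method="rate"), basis="p_vfa"
        )
        payload = {
            "ratios": ratios.as_dict(),
            "betweenness": stoichiometry.betweenness_check(ratios),
            "pao_fraction_endpoint": est_end.f_pao,
            "pao_fraction_rate": est_rate.f_pao,
        }
        path = outdir / "stoichiometry.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        outputs = [path] + ([outdir / "cycle.csv"] if not scfg.get("cycle_csv") else [])
        record_stage("stoich", dict(scfg), outputs)

    # -- probes --------------------------------------------------------------
    def stage_probe() -> None:
        pcfg = cfg.get("probes", {})
        probes = (
            probe_match.read_probe_tsv(pcfg["probe_tsv"])
            if pcfg.get("probe_tsv")
            else list(probe_match.DESIGNED_PROBES)
        )
        outputs = []
        if pcfg.get("sequences_fasta") and pcfg.get("taxonomy_tsv"):
            from Bio import SeqIO

            tax = {}
            import pandas as pd

            for row in pd.read_csv(pcfg["taxonomy_tsv"], sep="\t").itertuples(index=False):
                tax[str(row.sequence_id)] = str(row.taxonomy_label)
            seqs = [
                (rec.id, tax.get(rec.id, "unknown"), str(rec.seq))
                for rec in SeqIO.parse(pcfg["sequences_fasta"], "fasta")
            ]
            table = probe_match.coverage_table(
                probes, seqs, max_mismatch=int(pcfg.get("max_mismatch", 0))
            )
            path = outdir / "probe_coverage.tsv"
            table.to_csv(path, sep="\t", index=False)
            outputs.append(path)
        checks = {}
        by_name = {p.name: p for p in probes}
        for p in probes:
            for comp in p.competitors:
                if comp in by_name:
                    dist, pos = probe_match.competitor_check(p, by_name[comp])
                    checks[f"{p.name}:{comp}"] = {"distance": dist, "positions": pos}
        path = outdir / "probe_checks.json"
        path.write_text(json.dumps(checks, indent=2, sort_keys=True))
        outputs.append(path)
        record_stage("probe", {"n_probes": len(probes)}, outputs)

    all_stages: dict[str, Callable[[], None]] = {
        "community": stage_community,
        "reads": stage_reads,
        "coverage": stage_coverage,
        "markers": stage_markers,
        "linkage": stage_linkage,
        "bin": stage_bin,
        "stats": stage_stats,
        "stoich": stage_stoich,
        "probe": stage_probe,
    }
    requested = cfg.get("stages") or list(all_stages)
    unknown = [s for s in requested if s not in all_stages]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    for name in all_stages:  # dependency order is the declaration order
        if name in requested:
            logger.info("running stage %s", name)
            guarded(name, all_stages[name])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
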