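"""End-to-end orchestration: one JSON config drives filter -> diversity ->
RoH -> introgression, with a summary JSON and an auditable stage log.

The pipeline starts from either a VCF on disk or an inline simulation
block, applies the study's site filters, and runs whichever stages are
enabled. Every run records the config hash, the global seed and the
package version; per-stage record counts in/out make the filtering
attrition auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence

from . import __version__
from . import divstats, introgression, roh, simdata, vcfio

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Single-run configuration; see ``from_dict`` for the JSON schema."""

    out_dir: str
    vcf: Optional[str] = None
    popmap: Optional[str] = None
    sim: Optional[simdata.SimConfig] = None
    seed: int = 0
    stages: Dict[str, bool] = field(
        default_factory=lambda: {
            "filter": True,
            "diversity": True,
            "roh": True,
            "introgression": True,
        }
    )
    filter: vcfio.FilterConfig = field(default_factory=vcfio.FilterConfig)
    roh_params: roh.RoHParams = field(default_factory=roh.RoHParams)
    exclude_chroms: List[str] = field(default_factory=lambda: ["S7"])
    window_bp: int = 20_000
    step_bp: int = 20_000
    min_sites: int = 100
    permutation_n: int = 10_000
    permutation_bin_bp: int = 1_000_000
    trios: List[Dict[str, Any]] = field(default_factory=list)
    tree: Optional[str] = None
    fbranch_outgroup: Optional[str] = None
    chrom_lengths: Optional[Dict[str, int]] = None

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and d["sim"] is not None:
            sim = dict(d["sim"])
            if "populations" in sim:
                sim["populations"] = [
                    simdata.PopulationSpec(**p) for p in sim["populations"]
                ]
            for key in ("introgression_tracts", "autozygous_tracts"):
                if key in sim:
                    sim[key] = [simdata.Tract(**t) for t in sim[key]]
            d["sim"] = simdata.SimConfig(**sim)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = vcfio.FilterConfig(**d["filter"])
        if "roh_params" in d and isinstance(d["roh_params"], dict):
            d["roh_params"] = roh.RoHParams(**d["roh_params"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def validate(self) -> None:
        if (self.vcf is None) == (self.sim is None):
            raise ValueError("exactly one of 'vcf' or 'sim' must be given")
        if self.vcf is not None:
            if not os.path.exists(self.vcf):
                raise FileNotFoundError(self.vcf)
            if self.popmap is None or not os.path.exists(self.popmap):
                raise FileNotFoundError("popmap is required with an input VCF")
        if self.stages.get("introgression") and self.tree is not None:
            if "(" not in self.tree and not os.path.exists(self.tree):
                raise FileNotFoundError(self.tree)

    def config_hash(self) -> str:
        payload = _to_jsonable(self)
        payload.pop("out_dir", None)  # identifies the analysis, not the destination
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> Dict[str, Any]:
    """Execute the enabled stages in dependency order and return the
    summary dict (also written to ``<out_dir>/summary.json``)."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    log: List[str] = []
    summary: Dict[str, Any] = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }

    def _write_partial_and_raise(stage: str, exc: Exception) -> None:
        with open(os.path.join(cfg.out_dir, "FAILED"), "w") as fh:
            fh.write(f"stage={stage}\nerror={exc}\n")
        _flush(cfg, summary, log)
        raise StageError(stage, exc) from exc

    # --- input ------------------------------------------------------------
    try:
        if cfg.sim is not None:
            sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
            gm, pm, truth = simdata.write_dataset(sim_cfg, cfg.out_dir, prefix="sim")
            summary["input"] = {"source": "simulated", "truth": truth.as_dict()}
            chrom_lengths = dict(sim_cfg.chromosomes)
        else:
            gm = vcfio.read_vcf(cfg.vcf, biallelic_only=cfg.filter.biallelic_only)
            pm = vcfio.read_population_map(cfg.popmap)
            pm.validate_against(gm)
            summary["input"] = {"source": cfg.vcf}
            chrom_lengths = cfg.chrom_lengths or {
                c: int(gm.sites.loc[gm.sites["chrom"] == c, "pos"].max())
                for c in dict.fromkeys(gm.sites["chrom"])
            }
        log.append(f"input: {gm.n_samples} samples x {gm.n_sites} sites")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        _write_partial_and_raise("input", exc)

    # --- filter -----------------------------------------------------------
    if cfg.stages.get("filter", True):
        try:
            gm, report = vcfio.filter_sites(gm, cfg.filter)
            vcfio.write_filter_report(
                report, os.path.join(cfg.out_dir, "filter_report.tsv")
            )
            summary["filter"] = report.as_dict()
            log.append(f"filter: {report.n_input} -> {report.n_output} sites")
        except Exception as exc:
            _write_partial_and_raise("filter", exc)

    # --- diversity --------------------------------------------------------
    if cfg.stages.get("diversity", True):
        try:
            het = divstats.population_heterozygosity(gm, pm)
            het.to_csv(
                os.path.join(cfg.out_dir, "heterozygosity.tsv"), sep="\t", index=False
            )
            stats = divstats.window_stats(
                gm, pm, cfg.window_bp, cfg.step_bp, cfg.min_sites
            )
            divstats.window_stats_frame(stats).to_csv(
                os.path.join(cfg.out_dir, "window_stats.tsv"), sep="\t", index=False
            )
            summary["diversity"] = {
                "heterozygosity": {
                    r.population: r.mean_heterozygosity for r in het.itertuples()
                },
                "n_windows": len(stats),
            }
            lineages = sorted(set(pm.lineage.values()))
            if len(lineages) >= 2:
                fst = divstats.hudson_fst(
                    gm, pm.by_lineage(lineages[0]), pm.by_lineage(lineages[1])
                )
                dxy = divstats.genome_wide_dxy(
                    gm, pm.by_lineage(lineages[0]), pm.by_lineage(lineages[1])
                )
                summary["diversity"]["fst_between_lineages"] = fst
                summary["diversity"]["dxy_between_lineages"] = dxy
            log.append(f"diversity: {len(stats)} windows")
        except Exception as exc:
            _write_partial_and_raise("diversity", exc)

    # --- RoH ---------------------------------------------------------------
    if cfg.stages.get("roh", True):
        try:
            segs = roh.detect_roh_all(gm, pm, cfg.roh_params, cfg.exclude_chroms)
            roh.segments_frame(segs).to_csv(
                os.path.join(cfg.out_dir, "roh_segments.tsv"), sep="\t", index=False
            )
            regions, span_report = roh.consensus_regions(segs, pm)
            roh.regions_frame(regions).to_csv(
                os.path.join(cfg.out_dir, "roh_consensus.bed"),
                sep="\t", index=False, header=False,
            )
            summary["roh"] = {
                "n_segments": len(segs),
                "n_segments_captive": sum(
                    1 for g in segs if pm.status[g.sample] == "captive"
                ),
                "n_segments_wild": sum(
                    1 for g in segs if pm.status[g.sample] == "wild"
                ),
                "consensus": span_report,
            }
            cap_unique = [r.interval() for r in regions if r.status == "captive-unique"]
            if cap_unique:
                perm = roh.roh_clustering_permutation(
                    cap_unique, chrom_lengths,
                    n=cfg.permutation_n, bin_bp=cfg.permutation_bin_bp, seed=cfg.seed,
                )
                summary["roh"]["permutation"] = perm.as_dict()
                with open(os.path.join(cfg.out_dir, "roh_permutation.json"), "w") as fh:
                    json.dump(perm.as_dict(), fh, indent=2)
            try:
                summary["roh"]["comparison"] = roh.compare_roh(segs, pm)
            except ValueError as why:
                summary["roh"]["comparison"] = {"skipped": str(why)}
            log.append(f"roh: {len(segs)} segments, {len(regions)} consensus regions")
        except Exception as exc:
            _write_partial_and_raise("roh", exc)

    # --- introgression ------------------------------------------------------
    if cfg.stages.get("introgression", True):
        try:
            intro: Dict[str, Any] = {}
            results = []
            for spec in cfg.trios:
                res = introgression.d_statistic(
                    gm, pm, [spec["p1"], spec["p2"], spec["p3"]], spec["outgroup"],
                    n_blocks=spec.get("n_blocks", 20),
                )
                results.append(res)
            if results:
                passed = introgression.bh_filter_trios(results)
                frame = introgression.trio_results_frame(results)
                frame.to_csv(
                    os.path.join(cfg.out_dir, "trios.tsv"), sep="\t", index=False
                )
                intro["trios"] = json.loads(frame.to_json(orient="records"))
                intro["n_trios_passed"] = len(passed)
                scan_spec = cfg.trios[0]
                scan = introgression.fdm_scan(
                    gm, pm,
                    [scan_spec["p1"], scan_spec["p2"], scan_spec["p3"]],
                    scan_spec["outgroup"],
                )
                introgression.fdm_scan_frame(scan).to_csv(
                    os.path.join(cfg.out_dir, "fdm_scan.tsv"), sep="\t", index=False
                )
                if scan:
                    tracts = introgression.fdm_outlier_tracts(scan)
                    with open(os.path.join(cfg.out_dir, "fdm_tracts.bed"), "w") as fh:
                        for c, s, e in tracts:
                            fh.write(f"{c}\t{s}\t{e}\n")
                    intro["fdm"] = {
                        "n_windows": len(scan),
                        "n_outlier_tracts": len(tracts),
                    }
            if cfg.tree is not None and cfg.fbranch_outgroup is not None:
                fb = introgression.f_branch(cfg.tree, gm, pm, cfg.fbranch_outgroup)
                fb.frame().to_csv(
                    os.path.join(cfg.out_dir, "fbranch.tsv"), sep="\t"
                )
                branch, donor, value = fb.max_cell()
                intro["fbranch_max"] = {
                    "branch": branch, "donor": donor, "value": value,
                }
            summary["introgression"] = intro
            log.append(f"introgression: {len(results)} trios")
        except Exception as exc:
            _write_partial_and_raise("introgression", exc)

    _flush(cfg, summary, log)
    return summary


def _flush(cfg: PipelineConfig, summary: Dict[str, Any], log: List[str]) -> None:
    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
        fh.write("\n")
    with open(os.path.join(cfg.out_dir, "pipeline.log"), "w") as fh:
        fh.write(f"hermetia {__version__} seed={cfg.seed} config={cfg.config_hash()}\n")
        for line in log:
            fh.write(line + "\n")
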