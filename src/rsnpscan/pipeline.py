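"""Configuration-driven orchestration of the full rSNP pipeline.

Stages run in discovery order: heterozygous-site calling (ChIP, RNA) ->
asymmetry statistics -> promoter/enhancer target mapping -> ASB/ASE join
-> weighted-z + logistic scoring -> panel selection -> annotation
summaries, with optional NHD marker discovery when a genotype matrix is
supplied. Every stage writes a TSV into the run directory; a manifest
records the config hash, seed, per-stage row counts and output hashes.
Stages are re-used on rerun when their input hash is unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import allelic, annotate, linkage, scoring
from . import io as io_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths plus every published threshold, all overridable."""

    chip_counts: str = ""
    rna_counts: str = ""
    gene_models: str = ""
    enhancers: str = ""
    eqtl_catalog: str = ""
    gwas_catalog: str = ""
    genotypes: str = ""  # optional; enables the linkage stage
    position_mask: str = ""  # optional indel-proximity exclusion list

    min_minor_reads: int = 10
    p_join: float = 0.1
    padj_event: float = 0.1
    or_threshold: float = 1.5
    combined_p_cutoff: float | None = None
    pp_cutoff: float = scoring.DEFAULT_PP_CUTOFF
    nhd_gwas: float = 0.001
    nhd_marker: float = 0.1
    cp_min: float = 0.9
    max_markers: int = 10
    het_fraction: float = 0.10
    min_individuals: int = 6
    min_minor_carriers: int = 3
    n_ranks: int = 100
    de_padj: float = 0.1
    weight_mode: str = "coverage"
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunResult:
    outdir: Path
    manifest: dict
    tables: dict = field(default_factory=dict)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageRunner:
    """Writes each stage's TSV and reuses it when the input hash matches."""

    def __init__(self, outdir: Path, previous: dict):
        self.outdir = outdir
        self.previous = previous.get("stages", {})
        self.stages: dict = {}

    def run(self, name: str, input_hash: str, compute) -> pd.DataFrame:
        path = self.outdir / f"{name}.tsv"
        prev = self.previous.get(name)
        if prev and prev.get("input_hash") == input_hash and path.exists():
            if _hash_file(path) == prev.get("output_hash"):
                logger.info("stage %s: reused cached output", name)
                df = pd.read_csv(path, sep="\t")
                self.stages[name] = prev
                return df
        df = compute()
        df.to_csv(path, sep="\t", index=False)
        self.stages[name] = {
            "input_hash": input_hash,
            "output_hash": _hash_file(path),
            "rows": int(len(df)),
        }
        logger.info("stage %s: %d rows", name, len(df))
        return df


def run_pipeline(config: PipelineConfig, outdir) -> RunResult:
    """Execute the pipeline end to end into ``outdir``.

    Any stage failure propagates with the stage name attached. Reruns
    with an identical config and inputs reuse cached stage outputs and
    produce an identical manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != config.digest():
            previous = {}
    runner = _StageRunner(outdir, previous)
    cfg_hash = config.digest()
    tables: dict = {}

    def stage(name, compute, extra_hash=""):
        try:
            tables[name] = runner.run(name, cfg_hash + extra_hash, compute)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return tables[name]

    # -- ingest ------------------------------------------------------------
    chip = io_mod.read_allele_counts(config.chip_counts, "chip")
    rna = io_mod.read_allele_counts(config.rna_counts, "rna")
    if config.position_mask:
        mask = io_mod.read_position_mask(config.position_mask)
        chip = io_mod.apply_position_mask(chip, mask)
        rna = io_mod.apply_position_mask(rna, mask)
    genes = io_mod.read_gene_models(config.gene_models)
    enhancers = io_mod.read_enhancers(config.enhancers) if config.enhancers else []
    eqtl = io_mod.read_catalog(config.eqtl_catalog, "eqtl")
    gwas = (
        io_mod.read_catalog(config.gwas_catalog, "gwas")
        if config.gwas_catalog
        else None
    )
    in_hash = hashlib.sha256(
        "".join(
            _hash_file(Path(p))
            for p in [
                config.chip_counts,
                config.rna_counts,
                config.gene_models,
                config.eqtl_catalog,
            ]
            if p
        ).encode()
    ).hexdigest()

    # -- het calling + asymmetry ------------------------------------------
    promoter_window = (config.promoter_upstream, config.promoter_downstream)

    het_chip = stage(
        "het_chip",
        lambda: allelic.call_heterozygous(chip, config.min_minor_reads),
        in_hash,
    )
    het_rna = stage(
        "het_rna",
        lambda: allelic.call_heterozygous(rna, config.min_minor_reads),
        in_hash,
    )
    asb = stage(
        "asb",
        lambda: allelic.asymmetry_table(
            het_chip, config.or_threshold, config.padj_event
        ),
        in_hash,
    )
    ase = stage(
        "ase",
        lambda: allelic.asymmetry_table(
            het_rna, config.or_threshold, config.padj_event
        ),
        in_hash,
    )

    # -- mapping + join + scoring -----------------------------------------
    asb_hits = asb[asb["p_value"] < config.p_join]
    targets = stage(
        "targets",
        lambda: scoring.map_asb_to_targets(asb_hits, genes, enhancers, promoter_window),
        in_hash,
    )
    candidates = stage(
        "candidates",
        lambda: scoring.join_asb_ase(targets, asb, ase, genes, config.p_join),
        in_hash,
    )
    if len(candidates) == 0:
        raise RuntimeError("pipeline stage 'candidates' produced no rSNP candidates")

    def compute_scored():
        scored = scoring.add_combined_score(candidates, config.weight_mode)
        model = scoring.EqtlLogit.from_catalog(scored, eqtl)
        results = model.fit()
        scored["predicted_probability"] = results.predict(scored)
        (outdir / "model.json").write_text(json.dumps(results.to_dict(), indent=1))
        return scored

    scored = stage("scored", compute_scored, in_hash)
    panel = stage(
        "panel",
        lambda: scoring.select_panel(
            scored, config.pp_cutoff, config.combined_p_cutoff
        ),
        in_hash,
    )

    # -- annotation summaries ---------------------------------------------
    panel_sites = scoring.unique_sites(panel)
    site_table = het_chip[het_chip["site_id"].isin(set(panel_sites["site_id"]))]
    regions = stage(
        "region_classes",
        lambda: annotate.classify_regions(site_table, genes, promoter_window),
        in_hash,
    )

    def compute_overlap():
        rows = []
        stage_sets = {
            "heterozygous": het_chip["site_id"],
            "asb": asb_hits["site_id"],
            "asb_and_ase": candidates["site_id"],
            "panel": panel_sites["site_id"],
        }
        for stage_name, sites in stage_sets.items():
            if len(sites) == 0:
                continue
            row = {"stage": stage_name, "n": len(pd.unique(sites))}
            n, frac = annotate.overlap_catalog(sites, eqtl)
            row["eqtl_hits"], row["eqtl_fraction"] = n, frac
            if gwas is not None:
                n, frac = annotate.overlap_catalog(sites, gwas)
                row["gwas_hits"], row["gwas_fraction"] = n, frac
            rows.append(row)
        return pd.DataFrame(rows)

    overlap = stage("catalog_overlap", compute_overlap, in_hash)

    # -- optional linkage stage -------------------------------------------
    if config.genotypes:
        matrix = io_mod.read_genotypes(config.genotypes)
        coding = [
            s
            for s in matrix.site_ids
            if any(
                annotate.classify_region(
                    matrix.sites.iloc[matrix.index_of(s)], genes, promoter_window
                ).classes
                & {"cds"}
            )
        ]

        def compute_markers():
            frames = []
            for rsnp in panel_sites["site_id"]:
                if rsnp not in matrix.site_ids or not coding:
                    continue
                pairs = linkage.select_markers(
                    rsnp,
                    coding,
                    matrix,
                    cp_min=config.cp_min,
                    nhd_max=config.nhd_marker,
                    max_markers=config.max_markers,
                )
                if pairs:
                    frames.append(linkage.linked_pairs_table(pairs))
            if frames:
                return pd.concat(frames, ignore_index=True)
            return linkage.linked_pairs_table([])

        stage("linked_markers", compute_markers, in_hash)

    manifest = {
        "version": __version__,
        "config_hash": cfg_hash,
        "inputs_hash": in_hash,
        "seed": config.seed,
        "stages": runner.stages,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    _ = (targets, regions, overlap)
    return RunResult(outdir=outdir, manifest=manifest, tables=tables)


def run_in_memory(study: dict, config: PipelineConfig | None = None) -> dict:
    """Run the discovery stages on in-memory study tables.

    ``study`` is the dict produced by :func:`rsnpscan.simulate.generate_study`
    (or equivalent tables loaded through :mod:`rsnpscan.io`). Returns the
    per-stage tables plus the fitted scoring results, without touching the
    filesystem. The file-based :func:`run_pipeline` adds caching and
    manifests on top of the same stage logic.
    """
    config = config or PipelineConfig()
    promoter_window = (config.promoter_upstream, config.promoter_downstream)
    het_chip = allelic.call_heterozygous(study["chip_counts"], config.min_minor_reads)
    het_rna = allelic.call_heterozygous(study["rna_counts"], config.min_minor_reads)
    asb = allelic.asymmetry_table(het_chip, config.or_threshold, config.padj_event)
    ase = allelic.asymmetry_table(het_rna, config.or_threshold, config.padj_event)
    asb_hits = asb[asb["p_value"] < config.p_join]
    targets = scoring.map_asb_to_targets(
        asb_hits, study["gene_models"], study.get("enhancers"), promoter_window
    )
    candidates = scoring.join_asb_ase(
        targets, asb, ase, study["gene_models"], config.p_join
    )
    scored = scoring.add_combined_score(candidates, config.weight_mode)
    results = scoring.EqtlLogit.from_catalog(scored, study["eqtl_catalog"]).fit()
    scored["predicted_probability"] = results.predict(scored)
    panel = scoring.select_panel(scored, config.pp_cutoff, config.combined_p_cutoff)
    return {
        "het_chip": het_chip,
        "het_rna": het_rna,
        "asb": asb,
        "ase": ase,
        "asb_hits": asb_hits,
        "targets": targets,
        "candidates": candidates,
        "scored": scored,
        "panel": panel,
        "model_results": results,
    }
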