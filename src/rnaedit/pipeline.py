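"""Pipeline orchestration: simulate -> filter -> pileup -> summarize -> compare -> loci.

Each stage reads its inputs from, and writes versioned TSVs into, a single
output directory, so stages can be re-run individually. All tabular outputs
are tab-separated with a header row and '.' for missing values; genomic
positions are written 1-based (genome-browser convention) and converted back
to the package's 0-based half-open coordinates on load. A run manifest
records the config hash, seed, and per-stage row counts; re-running with an
identical config reproduces byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import pysam
import yaml

from . import filtering, pileup as pileup_mod, simulate as sim_mod, stats as stats_mod
from .annotation import Annotation, load_annotation, write_gff3
from .models import EditSite, FilterParams, ReadSimConfig, ValidationError

log = logging.getLogger("rnaedit")

STAGES = ("validate", "simulate", "filter", "pileup", "summarize", "compare", "loci")
NA = "."


@dataclass
class SampleSheetRow:
    sample_id: str
    condition: str  # 'control' | 'radar'
    timepoint: int  # minutes; 0 = uninfected
    edited: bool = False  # simulator applies edit sites only when True
    alignments: str | None = None  # external SAM/BAM; None => simulated

    def __post_init__(self):
        if self.condition not in ("control", "radar"):
            raise ValidationError(
                f"sample {self.sample_id}: condition must be control|radar"
            )


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    expressed_threshold: int = 10
    q_threshold: float = 0.05
    background: float | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    samples: list[SampleSheetRow] = field(default_factory=list)
    simulate: dict[str, Any] | None = None
    genome: str | None = None
    annotation: str | None = None
    loci: str | None = None

    @classmethod
    def from_yaml(
        cls,
        path: str | Path,
        out_dir: str | Path | None = None,
        seed: int | None = None,
    ) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        samples = [
            SampleSheetRow(
                sample_id=str(s["id"]),
                condition=s.get("condition", "control"),
                timepoint=int(s.get("timepoint", 0)),
                edited=bool(s.get("edited", s.get("condition") == "radar")),
                alignments=s.get("alignments"),
            )
            for s in raw.get("samples", [])
        ]
        fp = FilterParams(**raw.get("filter", {}))
        cfg = cls(
            out_dir=Path(out_dir if out_dir is not None else raw.get("out_dir", "out")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            expressed_threshold=int(raw.get("expressed_threshold", 10)),
            q_threshold=float(raw.get("q_threshold", 0.05)),
            background=raw.get("background"),
            filter_params=fp,
            samples=samples,
            simulate=raw.get("simulate"),
            genome=raw.get("genome"),
            annotation=raw.get("annotation"),
            loci=raw.get("loci"),
        )
        cfg._raw = raw  # retained for the manifest hash
        return cfg

    def config_hash(self) -> str:
        raw = getattr(self, "_raw", {})
        canon = json.dumps(raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if not self.samples:
            raise ValidationError("config lists no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in sample sheet")
        if self.simulate is None:
            if not (self.genome and self.annotation):
                raise ValidationError(
                    "without a 'simulate' block the config must point at a "
                    "genome and an annotation"
                )
            for s in self.samples:
                if not s.alignments or not Path(s.alignments).exists():
                    raise ValidationError(
                        f"sample {s.sample_id}: alignments file missing "
                        f"({s.alignments})"
                    )


def _sample_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % 2**31)


class Pipeline:
    """Runs the analysis stages against one output directory."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.manifest_path = self.out / "manifest.json"
        self._manifest = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "stages": [],
        }

    # -- paths -------------------------------------------------------------
    def sample_dir(self, sample_id: str) -> Path:
        return self.out / "samples" / sample_id

    def _require(self, path: Path, produced_by: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing artifact {path}; run the '{produced_by}' stage first"
            )
        return path

    def _genome_path(self) -> Path:
        if self.cfg.simulate is not None:
            return self._require(self.out / "ref" / "genome.fa", "simulate")
        return Path(self.cfg.genome)

    def _annotation_path(self) -> Path:
        if self.cfg.simulate is not None:
            return self._require(self.out / "ref" / "annotation.gff3", "simulate")
        return Path(self.cfg.annotation)

    def _loci_path(self) -> Path | None:
        if self.cfg.loci:
            return Path(self.cfg.loci)
        auto = self.out / "ref" / "loci.tsv"
        return auto if auto.exists() else None

    # -- manifest ----------------------------------------------------------
    def _record(self, stage: str, outputs: dict[str, int]) -> None:
        self._manifest["stages"] = [
            s for s in self._manifest["stages"] if s["stage"] != stage
        ]
        self._manifest["stages"].append({"stage": stage, "rows": outputs})
        self.out.mkdir(parents=True, exist_ok=True)
        with open(self.manifest_path, "w") as fh:
            json.dump(self._manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def _write_tsv(self, df: pd.DataFrame, path: Path) -> int:
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")
        return len(df)

    # -- stages ------------------------------------------------------------
    def stage_validate(self) -> None:
        self.cfg.validate()
        self._record("validate", {"samples": len(self.cfg.samples)})

    def stage_simulate(self) -> None:
        if self.cfg.simulate is None:
            log.info("simulate: no simulate block in config; skipping")
            self._record("simulate", {})
            return
        sim = self.cfg.simulate
        scen = dict(sim.get("scenario", {}))
        spec, genes = sim_mod.build_scenario(seed=self.cfg.seed, **scen)
        genome, ann = sim_mod.generate_reference(spec, genes)
        decoy = sim.get("decoy")
        if decoy:
            genome = sim_mod.plant_decoy(
                genome, ann, decoy["gene"], int(decoy.get("copies", 1))
            )
        edit_sites = self._resolve_edit_sites(sim.get("edit_sites", []), genome, ann)

        ref_dir = self.out / "ref"
        ref_dir.mkdir(parents=True, exist_ok=True)
        sim_mod.write_fasta(genome, ref_dir / "genome.fa")
        write_gff3(ann, ref_dir / "annotation.gff3")
        if edit_sites:
            loci_rows = [
                {
                    "contig": ann.by_id[s.gene_id].contig,
                    "pos": ann.by_id[s.gene_id].transcript_to_genomic(s.offset) + 1,
                    "strand": ann.by_id[s.gene_id].strand,
                    "label": s.label or f"{s.gene_id}:{s.offset}",
                }
                for s in edit_sites
            ]
            self._write_tsv(pd.DataFrame(loci_rows), ref_dir / "loci.tsv")

        rows = {}
        for idx, sample in enumerate(self.cfg.samples):
            cfg = ReadSimConfig(
                read_length=int(sim.get("read_length", 75)),
                mean_depth=float(sim.get("mean_depth", 50)),
                error_rate=float(sim.get("error_rate", 0.001)),
                indel_read_fraction=float(sim.get("indel_read_fraction", 0.0)),
                seed=_sample_seed(self.cfg.seed, idx),
            )
            sites = edit_sites if sample.edited else []
            result = sim_mod.simulate_reads(genome, ann, sites, cfg)
            result.write(self.sample_dir(sample.sample_id))
            rows[sample.sample_id] = result.n_reads
            log.info("simulate: %s -> %d reads", sample.sample_id, result.n_reads)
        self._record("simulate", rows)

    def _resolve_edit_sites(
        self, entries: list[dict], genome: dict[str, str], ann: Annotation
    ) -> list[EditSite]:
        sites = []
        for e in entries:
            gene = ann.by_id.get(e["gene"])
            if gene is None:
                raise ValidationError(f"edit_sites: unknown gene {e['gene']!r}")
            offset = e.get("offset", "auto")
            if offset == "auto":  # middle adenosine of the transcript
                offs = sim_mod.adenosine_offsets(genome, gene)
                offset = int(offs[len(offs) // 2])
            sites.append(
                EditSite(
                    gene_id=gene.gene_id,
                    offset=int(offset),
                    true_rate=float(e["rate"]),
                    label=e.get("label", ""),
                )
            )
        return sites

    def stage_filter(self) -> None:
        ann = load_annotation(self._annotation_path())
        stats_rows = []
        counts = {}
        for sample in self.cfg.samples:
            sdir = self.sample_dir(sample.sample_id)
            sdir.mkdir(parents=True, exist_ok=True)
            aln = (
                Path(sample.alignments)
                if sample.alignments
                else self._require(sdir / "truth.sam", "simulate")
            )
            with pysam.AlignmentFile(str(aln), check_sq=False) as fh:
                header = fh.header
                kept, fstats = filtering.filter_alignments(fh, ann, self.cfg.filter_params)
            filtering.write_sam(kept, header, sdir / "kept.sam")
            stats_rows.append({"sample": sample.sample_id} | fstats.to_row())
            counts[sample.sample_id] = fstats.kept
            log.info(
                "filter: %s kept %d/%d", sample.sample_id, fstats.kept,
                fstats.counts["input"],
            )
        self._write_tsv(pd.DataFrame(stats_rows), self.out / "filter_stats.tsv")
        self._record("filter", counts)

    def stage_pileup(self) -> None:
        genome = sim_mod.read_fasta(self._genome_path())
        counts = {}
        for sample in self.cfg.samples:
            sdir = self.sample_dir(sample.sample_id)
            kept = self._require(sdir / "kept.sam", "filter")
            pm = pileup_mod.build_pileup(
                filtering._iter_alignments(kept),
                genome,
                self.cfg.filter_params.min_base_quality,
            )
            df = pm.to_dataframe()
            df["pos"] = df["pos"] + 1  # 1-based in files
            counts[sample.sample_id] = self._write_tsv(df, sdir / "pileup.tsv")
        self._record("pileup", counts)

    def _load_pileup(self, sample_id: str, genome) -> pileup_mod.PileupMatrix:
        path = self._require(self.sample_dir(sample_id) / "pileup.tsv", "pileup")
        df = pd.read_csv(path, sep="\t", na_values=NA)
        df["pos"] = df["pos"] - 1
        return pileup_mod.PileupMatrix.from_dataframe(df, genome)

    def stage_summarize(self) -> None:
        genome = sim_mod.read_fasta(self._genome_path())
        ann = load_annotation(self._annotation_path())
        rate_frames = []
        counts = {}
        for sample in self.cfg.samples:
            sdir = self.sample_dir(sample.sample_id)
            pm = self._load_pileup(sample.sample_id, genome)
            site_df = pileup_mod.site_stats_table(pm, ann)
            rates = stats_mod.transcriptome_rates(
                site_df,
                self.cfg.expressed_threshold,
                sample=sample.sample_id,
                timepoint=sample.timepoint,
            )
            background = (
                self.cfg.background
                if self.cfg.background is not None
                else stats_mod.estimate_background(rates)
            )
            calls = stats_mod.call_sites(
                site_df,
                background_rate=background,
                q_threshold=self.cfg.q_threshold,
                expressed_threshold=self.cfg.expressed_threshold,
            )
            out_sites = site_df.copy()
            out_sites["pos"] = out_sites["pos"] + 1
            out_calls = calls.copy()
            out_calls["pos"] = out_calls["pos"] + 1
            self._write_tsv(out_sites, sdir / "site_stats.tsv")
            self._write_tsv(rates, sdir / "class_rates.tsv")
            counts[sample.sample_id] = self._write_tsv(
                out_calls, sdir / "site_calls.tsv"
            )
            rate_frames.append(rates)
            log.info(
                "summarize: %s background=%.3g called=%d/%d",
                sample.sample_id, background,
                int(calls["called_edited"].sum()) if len(calls) else 0, len(calls),
            )
        self._write_tsv(
            pd.concat(rate_frames, ignore_index=True), self.out / "class_rates.tsv"
        )
        self._record("summarize", counts)

    def _load_sample_results(self) -> list[stats_mod.SampleResult]:
        results = []
        for sample in self.cfg.samples:
            sdir = self.sample_dir(sample.sample_id)
            calls = pd.read_csv(
                self._require(sdir / "site_calls.tsv", "summarize"),
                sep="\t", na_values=NA,
            )
            if len(calls):
                calls["pos"] = calls["pos"] - 1
                calls["called_edited"] = calls["called_edited"].astype(bool)
            rates = pd.read_csv(sdir / "class_rates.tsv", sep="\t", na_values=NA)
            results.append(
                stats_mod.SampleResult(
                    sample.sample_id, sample.condition, sample.timepoint, calls, rates
                )
            )
        return results

    def stage_compare(self) -> None:
        comparison, summary = stats_mod.compare_conditions(self._load_sample_results())
        out_comp = comparison.copy()
        if len(out_comp):
            out_comp["pos"] = out_comp["pos"] + 1
        n = self._write_tsv(out_comp, self.out / "comparison.tsv")
        self._write_tsv(summary, self.out / "comparison_summary.tsv")
        self._record("compare", {"comparison": n, "summary": len(summary)})

    def stage_loci(self) -> None:
        loci_path = self._loci_path()
        if loci_path is None:
            log.info("loci: no locus list configured; skipping")
            self._record("loci", {})
            return
        genome = sim_mod.read_fasta(self._genome_path())
        loci = stats_mod.load_loci(loci_path)
        pileups = {
            s.sample_id: self._load_pileup(s.sample_id, genome)
            for s in self.cfg.samples
        }
        report = stats_mod.targeted_report(
            pileups, loci, self.cfg.expressed_threshold
        )
        n = self._write_tsv(report, self.out / "loci_report.tsv")
        self._record("loci", {"loci_report": n})

    def run(self, stages: list[str] | None = None) -> None:
        for stage in stages or STAGES:
            t0 = time.monotonic()
            getattr(self, f"stage_{stage}")()
            log.info("stage %s done in %.1fs", stage, time.monotonic() - t0)


def run_pipeline(
    config_path: str | Path,
    stages: list[str] | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> Pipeline:
    cfg = PipelineConfig.from_yaml(config_path, out_dir=out_dir, seed=seed)
    pipe = Pipeline(cfg)
    pipe.run(stages)
    return pipe


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="[%(name)s] %(message)s",
    )
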