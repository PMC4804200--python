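"""End-to-end orchestration: simulate -> recruit -> expression -> selection.

A single YAML config drives the whole run.  One global seed
deterministically derives every per-stage seed (via numpy SeedSequence on
``[global_seed, stage_index, item_index]``), so identical configs produce
byte-identical outputs, recorded in a run manifest with per-file row
counts and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    aggregate_clusters,
    build_count_table,
    cluster_map_from_annotations,
    count_metagenome_per_gene,
    count_transcripts_per_gene,
    normalize_by_housekeeping,
    normalize_by_metagenome,
    regress_clusters,
)
from .io_formats import (
    read_annotations,
    read_fasta,
    read_tabular_alignments,
    write_annotations,
    write_fasta,
    write_results,
    write_tabular_alignments,
)
from .recruitment import FilterConfig, recruit
from .selection import analyze_pair, genome_summary, read_codon_pairs, results_to_frame, write_codon_pairs
from .synthetic_community import (
    CommunityConfig,
    CodonSimConfig,
    ReadSimConfig,
    simulate_codon_pair,
    simulate_genome_pair,
    simulate_reads,
)

__all__ = [
    "ConfigError",
    "PipelineError",
    "PipelineConfig",
    "SampleSpec",
    "RunManifest",
    "validate_config",
    "run_all",
    "derive_seed",
]

STAGES = ("simulate", "recruit", "expression", "selection")


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


class PipelineError(RuntimeError):
    """A stage failed; the failing stage is named in the message."""


def derive_seed(global_seed: int, *path: int) -> int:
    """Deterministically derive a sub-seed from the global seed and an
    integer path (stage index, item index, ...)."""
    ss = np.random.SeedSequence([int(global_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1, np.uint32)[0])


@dataclass(frozen=True)
class SampleSpec:
    name: str
    mode: str  # MG or MT
    n_reads: int
    lineage_weights: Mapping[str, float]
    error_rate: float = 0.005
    read_length: int = 100


@dataclass(frozen=True)
class ExpressionSpec:
    pairs: tuple[tuple[str, str], ...] = ()  # (mt_sample, mg_sample)
    hk_genes: tuple[str, ...] = ("recA", "gyrB")
    hk_method: str = "mean"


@dataclass(frozen=True)
class SelectionSpec:
    n_pairs: int = 40
    n_codons: int = 300
    omega: float = 0.15
    expected_ds: float = 0.3
    B: int = 1000
    alpha: float = 0.05
    pairs_fasta: str | None = None  # pre-aligned pairs instead of simulation


@dataclass(frozen=True)
class InputSpec:
    """File-driven recruitment inputs (used when no community is simulated)."""

    alignments: str
    reads: str
    annotations: str
    contig_map: str


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    stages: tuple[str, ...]
    community: CommunityConfig | None
    samples: tuple[SampleSpec, ...]
    filter: FilterConfig
    expression: ExpressionSpec
    selection: SelectionSpec
    inputs: InputSpec | None = None

    def echo(self) -> dict:
        def unpack(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {k: unpack(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [unpack(v) for v in obj]
            return obj

        # out_dir is deliberately not echoed: the run definition (and hence
        # the manifest) is identical wherever the outputs land
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "community": unpack(self.community) if self.community else None,
            "samples": [unpack(s) for s in self.samples],
            "filter": unpack(self.filter),
            "expression": unpack(self.expression),
            "selection": unpack(self.selection),
            "inputs": unpack(self.inputs) if self.inputs else None,
        }


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_TOP_KEYS = {"seed", "out_dir", "stages", "community", "samples", "filter",
             "expression", "selection", "inputs"}
_COMMUNITY_KEYS = {"genome_length", "n_genes", "gene_length", "divergence",
                   "gc_content", "rrna_intervals", "its_intervals"}
_SAMPLE_KEYS = {"name", "mode", "n_reads", "lineage_weights", "error_rate", "read_length"}
_FILTER_KEYS = {"min_pident", "max_evalue", "min_query_coverage", "population_identity",
                "histogram_lo", "histogram_hi", "histogram_step"}
_EXPRESSION_KEYS = {"pairs", "hk_genes", "hk_method"}
_SELECTION_KEYS = {"n_pairs", "n_codons", "omega", "expected_ds", "B", "alpha", "pairs_fasta"}
_INPUT_KEYS = {"alignments", "reads", "annotations", "contig_map"}


def _unknown(raw: Mapping, allowed: set[str], where: str, errors: list[str]) -> None:
    for key in raw:
        if key not in allowed:
            errors.append(f"{where}: unknown key {key!r}")


def validate_config(source: str | Path | Mapping) -> PipelineConfig:
    """Parse, default-fill and validate a pipeline config.

    Errors are collected exhaustively (not first-failure) and raised
    together as :class:`ConfigError`.  Unknown keys are rejected.
    """
    if isinstance(source, Mapping):
        raw: dict = dict(source)
        base = Path(".")
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError([f"config file {path} does not exist"])
        with open(path) as handle:
            loaded = yaml.safe_load(handle)
        raw = dict(loaded) if loaded else {}
        base = path.parent

    errors: list[str] = []
    _unknown(raw, _TOP_KEYS, "top level", errors)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: expected integer, got {seed!r}")
        seed = 0
    out_dir = raw.get("out_dir", "symbiorecruit_run")
    if not isinstance(out_dir, str):
        errors.append(f"out_dir: expected string, got {out_dir!r}")
        out_dir = "symbiorecruit_run"

    stages_raw = raw.get("stages", list(STAGES))
    stages: list[str] = []
    if not isinstance(stages_raw, list):
        errors.append("stages: expected a list")
    else:
        for s in stages_raw:
            if s not in STAGES:
                errors.append(f"stages: unknown stage {s!r}")
            else:
                stages.append(s)

    community = None
    if "community" in raw and raw["community"] is not None:
        c = raw["community"]
        if not isinstance(c, Mapping):
            errors.append("community: expected a mapping")
        else:
            _unknown(c, _COMMUNITY_KEYS, "community", errors)
            kwargs = {k: c[k] for k in _COMMUNITY_KEYS if k in c}
            for key in ("rrna_intervals", "its_intervals"):
                if key in kwargs:
                    try:
                        kwargs[key] = tuple((int(s), int(e)) for s, e in kwargs[key])
                    except (TypeError, ValueError):
                        errors.append(f"community.{key}: expected a list of [start, end] pairs")
                        del kwargs[key]
            try:
                community = CommunityConfig(seed=derive_seed(seed, 0), **kwargs)
            except Exception as exc:
                errors.append(f"community: {exc}")

    samples: list[SampleSpec] = []
    sample_names: set[str] = set()
    for i, s in enumerate(raw.get("samples", []) or []):
        where = f"samples[{i}]"
        if not isinstance(s, Mapping):
            errors.append(f"{where}: expected a mapping")
            continue
        _unknown(s, _SAMPLE_KEYS, where, errors)
        name = s.get("name")
        if not name or not isinstance(name, str):
            errors.append(f"{where}: missing or invalid 'name'")
            continue
        if name in sample_names:
            errors.append(f"{where}: duplicate sample name {name!r}")
            continue
        mode = s.get("mode")
        if mode not in ("MG", "MT"):
            errors.append(f"{where}: mode must be MG or MT, got {mode!r}")
            continue
        n_reads = s.get("n_reads")
        if not isinstance(n_reads, int) or n_reads <= 0:
            errors.append(f"{where}: n_reads must be a positive integer")
            continue
        weights = s.get("lineage_weights", {"A": 0.5, "B": 0.5})
        if not isinstance(weights, Mapping) or abs(sum(weights.values()) - 1.0) > 1e-9:
            errors.append(f"{where}: lineage_weights must sum to 1")
            continue
        error_rate = s.get("error_rate", 0.005)
        if not isinstance(error_rate, (int, float)) or not (0 <= error_rate < 1):
            errors.append(f"{where}: error_rate must be in [0, 1)")
            continue
        read_length = s.get("read_length", 100)
        if not isinstance(read_length, int) or read_length <= 0:
            errors.append(f"{where}: read_length must be a positive integer")
            continue
        sample_names.add(name)
        samples.append(
            SampleSpec(
                name=name, mode=mode, n_reads=n_reads,
                lineage_weights=dict(weights), error_rate=float(error_rate),
                read_length=read_length,
            )
        )

    f = raw.get("filter", {}) or {}
    filter_cfg = FilterConfig()
    if not isinstance(f, Mapping):
        errors.append("filter: expected a mapping")
    else:
        _unknown(f, _FILTER_KEYS, "filter", errors)
        kwargs = {}
        n_before = len(errors)
        for key in _FILTER_KEYS:
            if key in f:
                value = f[key]
                if not isinstance(value, (int, float)):
                    errors.append(f"filter.{key}: expected a number, got {value!r}")
                else:
                    kwargs[key] = float(value)
        # per-key range checks first, so every violation is reported
        if not (0.0 < kwargs.get("min_query_coverage", 0.9) <= 1.0):
            errors.append("filter.min_query_coverage: must be in (0, 1]")
        for key in ("min_pident", "population_identity"):
            if key in kwargs and not (0.0 <= kwargs[key] <= 100.0):
                errors.append(f"filter.{key}: must be a percentage in [0, 100]")
        if kwargs.get("min_pident", 50.0) > kwargs.get("population_identity", 95.0):
            errors.append("filter.min_pident: must not exceed filter.population_identity")
        if len(errors) == n_before:
            try:
                filter_cfg = FilterConfig(**kwargs)
            except ValueError as exc:
                errors.append(f"filter: {exc}")

    e = raw.get("expression", {}) or {}
    expression = ExpressionSpec()
    if not isinstance(e, Mapping):
        errors.append("expression: expected a mapping")
    else:
        _unknown(e, _EXPRESSION_KEYS, "expression", errors)
        pairs: list[tuple[str, str]] = []
        for j, p in enumerate(e.get("pairs", []) or []):
            if not isinstance(p, Mapping) or "mt" not in p or "mg" not in p:
                errors.append(f"expression.pairs[{j}]: expected {{mt: ..., mg: ...}}")
                continue
            mt, mg = p["mt"], p["mg"]
            for role, sname, want in (("mt", mt, "MT"), ("mg", mg, "MG")):
                spec = next((s for s in samples if s.name == sname), None)
                if spec is None:
                    errors.append(f"expression.pairs[{j}].{role}: unknown sample {sname!r}")
                elif spec.mode != want:
                    errors.append(
                        f"expression.pairs[{j}].{role}: sample {sname!r} is {spec.mode}, expected {want}"
                    )
            pairs.append((mt, mg))
        hk_method = e.get("hk_method", "mean")
        if hk_method not in ("mean", "sum", "geometric"):
            errors.append(f"expression.hk_method: unknown method {hk_method!r}")
            hk_method = "mean"
        expression = ExpressionSpec(
            pairs=tuple(pairs),
            hk_genes=tuple(e.get("hk_genes", ("recA", "gyrB"))),
            hk_method=hk_method,
        )

    sel = raw.get("selection", {}) or {}
    selection = SelectionSpec()
    if not isinstance(sel, Mapping):
        errors.append("selection: expected a mapping")
    else:
        _unknown(sel, _SELECTION_KEYS, "selection", errors)
        kwargs = {}
        for key, typ in (("n_pairs", int), ("n_codons", int), ("B", int)):
            if key in sel:
                if not isinstance(sel[key], int) or sel[key] <= 0:
                    errors.append(f"selection.{key}: expected a positive integer")
                else:
                    kwargs[key] = sel[key]
        for key in ("omega", "expected_ds", "alpha"):
            if key in sel:
                if not isinstance(sel[key], (int, float)) or sel[key] <= 0:
                    errors.append(f"selection.{key}: expected a positive number")
                else:
                    kwargs[key] = float(sel[key])
        if "alpha" in kwargs and kwargs["alpha"] >= 1:
            errors.append("selection.alpha: must be < 1")
            del kwargs["alpha"]
        if sel.get("pairs_fasta") is not None:
            pf = base / str(sel["pairs_fasta"])
            if not pf.exists():
                errors.append(f"selection.pairs_fasta: file {pf} does not exist")
            kwargs["pairs_fasta"] = str(pf)
        selection = SelectionSpec(**kwargs)

    inputs = None
    if "inputs" in raw and raw["inputs"] is not None:
        inp = raw["inputs"]
        if not isinstance(inp, Mapping):
            errors.append("inputs: expected a mapping")
        else:
            _unknown(inp, _INPUT_KEYS, "inputs", errors)
            missing = [k for k in _INPUT_KEYS if k not in inp]
            if missing:
                errors.append(f"inputs: missing required path(s) {sorted(missing)}")
            else:
                paths = {k: str(base / str(inp[k])) for k in _INPUT_KEYS}
                for k, p in sorted(paths.items()):
                    if not Path(p).exists():
                        errors.append(f"inputs.{k}: file {p} does not exist")
                inputs = InputSpec(**paths)

    if "recruit" in stages and community is None and inputs is None:
        errors.append("recruit stage requires either a 'community' (synthetic) or 'inputs' (files)")
    if community is not None and "simulate" in stages and not samples:
        errors.append("simulate stage requires at least one entry under 'samples'")
    if "expression" in stages and community is not None and not expression.pairs:
        errors.append("expression stage requires expression.pairs naming MT/MG samples")

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        stages=tuple(s for s in STAGES if s in stages),
        community=community,
        samples=tuple(samples),
        filter=filter_cfg,
        expression=expression,
        selection=selection,
        inputs=inputs,
    )


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    version: str
    stage_order: list[str] = field(default_factory=list)
    stages: dict[str, dict] = field(default_factory=dict)
    files: list[dict] = field(default_factory=list)
    status: str = "OK"

    def record_files(self, out_dir: Path, stage: str, entries: list[dict]) -> None:
        for entry in entries:
            payload = (out_dir / stage / entry["file"]).read_bytes()
            self.files.append(
                {
                    "file": f"{stage}/{entry['file']}",
                    "rows": entry["rows"],
                    "sha256": hashlib.sha256(payload).hexdigest(),
                }
            )

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")
        return path


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def _frame_manifest(out_dir: Path, stage: str, tables: dict[str, pd.DataFrame]) -> list[dict]:
    return write_results(tables, out_dir / stage)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages end-to-end.

    Identical config (including seeds) produces byte-identical outputs.  A
    stage failure marks the manifest FAILED (partial outputs are kept) and
    raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.echo(), version=__version__)

    pair = None
    read_sets: dict[str, Any] = {}
    recruit_results: dict[str, Any] = {}
    current = "setup"
    try:
        if "simulate" in config.stages and config.community is not None:
            current = "simulate"
            pair, read_sets = _stage_simulate(config, out_dir, manifest)
        if "recruit" in config.stages:
            current = "recruit"
            recruit_results = _stage_recruit(config, out_dir, manifest, pair, read_sets)
        if "expression" in config.stages and config.community is not None:
            current = "expression"
            _stage_expression(config, out_dir, manifest, pair, read_sets, recruit_results)
        if "selection" in config.stages:
            current = "selection"
            _stage_selection(config, out_dir, manifest)
    except Exception as exc:
        manifest.status = f"FAILED at stage {current}: {exc}"
        manifest.write(out_dir)
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
    manifest.write(out_dir)
    return manifest


def _stage_simulate(config: PipelineConfig, out_dir: Path, manifest: RunManifest):
    stage_dir = out_dir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    pair = simulate_genome_pair(config.community)
    write_fasta([pair.ancestor], stage_dir / "ancestor.fasta")
    write_fasta(list(pair.genomes.values()), stage_dir / "genomes.fasta")
    write_annotations(pair.annotations_for("A"), stage_dir / "annotations.gff3")
    with open(stage_dir / "config_echo.yaml", "w") as handle:
        yaml.safe_dump(config.echo(), handle, sort_keys=True)

    read_sets = {}
    rows = {"genomes": 2, "annotations": len(pair.annotations)}
    for i, spec in enumerate(config.samples):
        sim_cfg = ReadSimConfig(
            n_reads=spec.n_reads,
            mode=spec.mode,
            read_length=spec.read_length,
            lineage_weights=spec.lineage_weights,
            error_rate=spec.error_rate,
            seed=derive_seed(config.seed, 1, i),
            read_id_prefix=spec.name,
        )
        rs = simulate_reads(pair, sim_cfg)
        read_sets[spec.name] = rs
        write_fasta(rs.reads, stage_dir / f"reads_{spec.name}.fasta")
        write_tabular_alignments(rs.truth_alignments, stage_dir / f"alignments_{spec.name}.tsv")
        truth_frame = pd.DataFrame(
            [
                {
                    "read_id": t.read_id,
                    "origin_lineage": t.origin_lineage,
                    "origin_start": t.origin_start,
                    "origin_end": t.origin_end,
                    "n_errors": t.n_errors,
                }
                for t in rs.truth
            ]
        )
        entries = write_results({f"truth_{spec.name}": truth_frame}, stage_dir)
        manifest.record_files(out_dir, "simulate", entries)
        rows[f"reads_{spec.name}"] = spec.n_reads
    manifest.stage_order.append("simulate")
    manifest.stages["simulate"] = {
        "rows": rows,
        "realized_divergence": pair.realized_divergence,
        "n_variant_positions": int(len(pair.variant_positions)),
    }
    return pair, read_sets


def _load_file_inputs(config: PipelineConfig):
    inp = config.inputs
    contig_map = {}
    with open(inp.contig_map) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig, genome = line.split("\t")[:2]
            contig_map[contig] = genome
    records = read_tabular_alignments(inp.alignments, contig_map)
    reads = read_fasta(inp.reads)
    read_lengths = {r.id: len(r) for r in reads}
    annotations = read_annotations(inp.annotations, "gff3")
    genome_ids = sorted(set(contig_map.values()))
    masks = {
        g: [(a.start, a.end) for a in annotations if a.feature_kind in ("rRNA", "ITS")]
        for g in genome_ids
    }
    # genome lengths approximated by the furthest annotated/aligned position
    genome_lengths = {}
    for g in genome_ids:
        hi = max(
            [r.subject_end for r in records if r.genome_id == g]
            + [a.end for a in annotations],
            default=0,
        )
        genome_lengths[g] = hi
    return [("input", records, read_lengths)], masks, genome_lengths


def _stage_recruit(config, out_dir, manifest, pair, read_sets):
    if pair is not None:
        masks = pair.masks
        genome_lengths = pair.genome_lengths
        jobs = [
            (name, rs.truth_alignments, rs.read_lengths) for name, rs in read_sets.items()
        ]
    else:
        jobs, masks, genome_lengths = _load_file_inputs(config)

    results = {}
    summary_rows, hist_rows, assigned_rows, log_rows = [], [], [], []
    for name, records, read_lengths in jobs:
        res = recruit(records, read_lengths, masks, genome_lengths, config.filter)
        results[name] = res
        for g, summ in sorted(res.summaries.items()):
            summary_rows.append(
                {
                    "sample": name,
                    "genome": g,
                    "n_assigned": summ.n_assigned,
                    "n_population": summ.n_population,
                    "covered_positions": summ.covered_positions,
                    "genome_length": summ.genome_length,
                    "recovery_pct": summ.recovery_pct,
                }
            )
            hf = summ.histogram.as_frame()
            hf.insert(0, "genome", g)
            hf.insert(0, "sample", name)
            hist_rows.append(hf)
        for a in res.assigned:
            assigned_rows.append(
                {
                    "sample": name,
                    "read_id": a.read_id,
                    "genome": a.genome_id or "",
                    "ambiguous": int(a.ambiguous),
                    "pident": a.record.pident if a.record else float("nan"),
                    "subject_start": a.record.subject_start if a.record else -1,
                    "subject_end": a.record.subject_end if a.record else -1,
                }
            )
        log_rows.append(
            {
                "sample": name,
                "n_input": res.filter_log.n_input,
                "n_retained": res.filter_log.n_retained,
                "n_ambiguous": res.n_ambiguous,
                **{f"removed_{k}": v for k, v in res.filter_log.removed.items()},
            }
        )
    tables = {
        "recruitment_summary": pd.DataFrame(summary_rows),
        "histograms": pd.concat(hist_rows, ignore_index=True),
        "assigned_reads": pd.DataFrame(assigned_rows),
        "filter_log": pd.DataFrame(log_rows),
    }
    entries = _frame_manifest(out_dir, "recruitment", tables)
    manifest.record_files(out_dir, "recruitment", entries)
    manifest.stage_order.append("recruit")
    manifest.stages["recruit"] = {
        "rows": {name: res.filter_log.n_input for name, res in results.items()},
        "bookkeeping": {
            name: {
                "retained_records": res.filter_log.n_retained,
                "reads_with_hits": len(res.assigned),
                "ambiguous": res.n_ambiguous,
                "assigned": sum(s.n_assigned for s in res.summaries.values()),
            }
            for name, res in results.items()
        },
    }
    return results


def _stage_expression(config, out_dir, manifest, pair, read_sets, recruit_results):
    annotations = pair.annotations
    cluster_map = cluster_map_from_annotations(annotations)
    count_rows, norm_rows, cluster_rows, regression_rows = [], [], [], []
    nif_by_sample: dict[str, dict[str, dict[str, int]]] = {}

    for mt_name, mg_name in config.expression.pairs:
        mt_res = recruit_results[mt_name]
        mg_res = recruit_results[mg_name]
        mt_depth = read_sets[mt_name].config.n_reads
        mg_depth = read_sets[mg_name].config.n_reads
        for g in sorted(pair.genomes):
            mt_assigned = [a for a in mt_res.assigned if a.genome_id == g]
            mg_assigned = [a for a in mg_res.assigned if a.genome_id == g]
            mt_counts = count_transcripts_per_gene(mt_assigned, annotations, config.filter)
            mg_counts = count_metagenome_per_gene(mg_assigned, annotations, config.filter)
            table = build_count_table(mt_counts, mg_counts)
            per_cell = normalize_by_housekeeping(
                table, config.expression.hk_genes, config.expression.hk_method
            )
            mg_norm = normalize_by_metagenome(table, mt_depth, mg_depth)
            for gene in table.gene_ids:
                count_rows.append(
                    {
                        "pair": f"{mt_name}|{mg_name}",
                        "genome": g,
                        "gene_id": gene,
                        "mt_count": int(table.frame.loc[gene, "mt_count"]),
                        "mg_count": int(table.frame.loc[gene, "mg_count"]),
                    }
                )
                norm_rows.append(
                    {
                        "pair": f"{mt_name}|{mg_name}",
                        "genome": g,
                        "gene_id": gene,
                        "per_cell": per_cell[gene],
                        "mg_norm": mg_norm[gene],
                    }
                )
            summary = aggregate_clusters(table, cluster_map)
            for cluster, row in summary.frame.iterrows():
                cluster_rows.append(
                    {
                        "pair": f"{mt_name}|{mg_name}",
                        "genome": g,
                        "cluster": cluster,
                        "transcript_count": int(row["transcript_count"]),
                        "relative_contribution_pct": row["relative_contribution_pct"],
                    }
                )
                nif_by_sample.setdefault(g, {}).setdefault(mt_name, {})[cluster] = int(
                    row["transcript_count"]
                )

    # regression of each non-nif cluster on the nif operon across MT samples
    for g, per_sample in sorted(nif_by_sample.items()):
        clusters = sorted({c for counts in per_sample.values() for c in counts})
        for cluster in clusters:
            if cluster == "nif_operon":
                continue
            points = [
                (counts.get("nif_operon", 0), counts.get(cluster, 0))
                for counts in per_sample.values()
            ]
            if len(points) < 3:
                continue
            try:
                fit = regress_clusters(points)
            except ValueError:
                continue
            regression_rows.append(
                {
                    "genome": g,
                    "cluster": cluster,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "p_value": fit.p_value,
                    "n": fit.n,
                }
            )

    tables = {
        "gene_counts": pd.DataFrame(count_rows),
        "normalized_expression": pd.DataFrame(norm_rows),
        "cluster_summary": pd.DataFrame(cluster_rows),
    }
    if regression_rows:
        tables["regression"] = pd.DataFrame(regression_rows)
    entries = _frame_manifest(out_dir, "expression", tables)
    manifest.record_files(out_dir, "expression", entries)
    manifest.stage_order.append("expression")
    manifest.stages["expression"] = {
        "rows": {name: len(df) for name, df in tables.items()}
    }


def _stage_selection(config, out_dir, manifest):
    sel = config.selection
    stage_dir = out_dir / "selection"
    stage_dir.mkdir(parents=True, exist_ok=True)
    if sel.pairs_fasta:
        pairs = read_codon_pairs(sel.pairs_fasta)
        truths = None
    else:
        pairs = []
        truths = []
        for i in range(sel.n_pairs):
            cfg = CodonSimConfig(
                n_codons=sel.n_codons,
                omega=sel.omega,
                expected_dS=sel.expected_ds,
                seed=derive_seed(config.seed, 3, i),
                gene_id=f"orth_{i:04d}",
            )
            p, t = simulate_codon_pair(cfg)
            pairs.append(p)
            truths.append(t)
        write_codon_pairs(pairs, stage_dir / "codon_pairs.fasta")

    results = [
        analyze_pair(p, B=sel.B, seed=derive_seed(config.seed, 4, i))
        for i, p in enumerate(pairs)
    ]
    summary = genome_summary(results, alpha=sel.alpha)
    tables = {
        "kaks_results": results_to_frame(results),
        "selection_summary": pd.DataFrame(
            [
                {
                    "n_genes": summary.n_genes,
                    "n_purifying_significant": summary.n_purifying_significant,
                    "n_positive_significant": summary.n_positive_significant,
                    "n_not_significant": summary.n_not_significant,
                    "alpha": summary.alpha,
                }
            ]
        ),
    }
    if truths is not None:
        tables["simulation_truth"] = pd.DataFrame(
            [
                {
                    "gene_id": p.gene_id,
                    "syn_events": t.syn_events,
                    "nonsyn_events": t.nonsyn_events,
                    "target_syn_events": t.target_syn_events,
                }
                for p, t in zip(pairs, truths)
            ]
        )
    entries = _frame_manifest(out_dir, "selection", tables)
    manifest.record_files(out_dir, "selection", entries)
    manifest.stage_order.append("selection")
    manifest.stages["selection"] = {
        "rows": {"pairs": len(pairs)},
        "summary": dataclasses.asdict(summary),
    }
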