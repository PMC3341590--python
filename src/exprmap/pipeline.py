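"""End-to-end orchestration from a declarative YAML run configuration.

A run config names input files (or a synthetic-data spec), the stages to
run and their parameters; :func:`run_pipeline` executes the configured
stages in order (simulate → normalize → train → enrich / spatial-test /
reproducibility / regions / overlay) and writes every artifact with a
provenance header (tool version, config hash, seed) sufficient to
regenerate it exactly.  Timestamps are deliberately kept out of outputs so
that reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ExprMapError
from . import io_formats, normalize as norm_mod, som as som_mod
from . import enrichment as enr_mod, spatial as spa_mod, regions as reg_mod
from . import synthetic as syn_mod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parsed run configuration; ``raw`` keeps the original mapping for hashing."""

    raw: dict
    seed: int
    output_dir: Path

    @classmethod
    def from_yaml(cls, path, seed_override: int | None = None) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ExprMapError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ExprMapError(f"config file {path} must contain a mapping")
        seed = int(seed_override if seed_override is not None else raw.get("seed", 0))
        raw["seed"] = seed
        out = Path(raw.get("output_dir", "."))
        return cls(raw=raw, seed=seed, output_dir=out)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> str:
        return f"exprmap v{__version__} config={self.config_hash} seed={self.seed}"


def _require_path(p, what: str) -> Path:
    path = Path(p)
    if not path.exists():
        raise ExprMapError(f"{what} not found: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the configured stages; returns {artifact name: path}.

    Stage errors propagate as :class:`ExprMapError` prefixed with the stage
    name; unconfigured stages are skipped.
    """
    cfg = config.raw
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.provenance()
    artifacts: dict[str, Path] = {}

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except ExprMapError as exc:
                raise ExprMapError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    matrix = None
    truth = None

    if "simulate" in cfg:
        @stage("simulate")
        def _():
            nonlocal matrix, truth
            params = dict(cfg["simulate"] or {})
            params.setdefault("seed", config.seed)
            if "experiment_blocks" in params:
                params["experiment_blocks"] = tuple(
                    (str(e), int(n)) for e, n in params["experiment_blocks"])
            spec = syn_mod.SyntheticSpec(**params)
            matrix, truth = syn_mod.generate_matrix(spec)
            io_formats.write_expression_matrix(
                matrix, outdir / "matrix.tsv", outdir / "experiments.tsv", header)
            syn_mod.write_truth(truth, outdir / "truth.tsv", header)
            artifacts["matrix"] = outdir / "matrix.tsv"
            artifacts["experiments"] = outdir / "experiments.tsv"
            artifacts["truth"] = outdir / "truth.tsv"
    elif "matrix" in cfg:
        @stage("input")
        def _():
            nonlocal matrix
            matrix = io_formats.read_expression_matrix(
                _require_path(cfg["matrix"], "expression matrix"),
                _require_path(cfg["experiments"], "experiments table"))

    if "normalize" in cfg and matrix is not None:
        @stage("normalize")
        def _():
            nonlocal matrix
            params = cfg["normalize"] or {}
            shift = params.get("shift_experiments", "all")
            plan = norm_mod.NormalizationPlan(
                None if shift in ("all", None) else set(shift))
            matrix = norm_mod.median_shift(matrix, plan)
            io_formats.write_expression_matrix(matrix, outdir / "normalized.tsv",
                                               None, header)
            artifacts["normalized"] = outdir / "normalized.tsv"

    som = None
    if "train" in cfg and matrix is not None:
        @stage("train")
        def _():
            nonlocal som
            params = dict(cfg["train"] or {})
            params.setdefault("seed", config.seed)
            som = som_mod.train(matrix, som_mod.SomConfig(**params))
            io_formats.write_map(som, outdir / "map.json",
                                 {"provenance": header})
            io_formats.write_assignment_tsv(som, outdir / "assignment.tsv", header)
            artifacts["map"] = outdir / "map.json"
            artifacts["assignment"] = outdir / "assignment.tsv"

    if "enrich" in cfg and som is not None:
        @stage("enrich")
        def _():
            params = cfg["enrich"] or {}
            ann = io_formats.read_annotations(
                _require_path(params["annotations"], "annotation table"),
                params.get("dialect", "two_column"))
            if params.get("obo"):
                ann = io_formats.propagate_annotations(
                    ann, _require_path(params["obo"], "ontology"))
            results = enr_mod.run_enrichment(som, ann,
                                             float(params.get("fdr", 0.05)))
            df = enr_mod.results_to_frame(results)
            path = outdir / "enrichment.tsv"
            with open(path, "w") as fh:
                fh.write(f"# {header}\n")
                df.to_csv(fh, sep="\t", index=False)
            artifacts["enrichment"] = path

    if "spatial" in cfg and som is not None:
        @stage("spatial-test")
        def _():
            params = cfg["spatial"] or {}
            sets = io_formats.read_gene_sets(
                _require_path(params["sets"], "gene sets"),
                params.get("dialect", "gmt"))
            n_samples = int(params.get("samples", 100))
            rows = []
            for i, gs in enumerate(sets):
                r = spa_mod.nonrandom_test(som, gs, n_samples=n_samples,
                                           n_tests=len(sets),
                                           seed=config.seed + i)
                rows.append(r)
            path = outdir / "spatial.tsv"
            with open(path, "w") as fh:
                fh.write(f"# {header}\n")
                fh.write("set_name\tn\td_observed\tn_samples\tp_raw\tp_corrected\tp_conservative\n")
                for r in rows:
                    fh.write(f"{r.set_name}\t{r.n}\t{r.d_observed:.6g}\t{r.n_samples}"
                             f"\t{r.p_raw:.6g}\t{r.p_corrected:.6g}\t{r.p_conservative:.6g}\n")
            artifacts["spatial"] = path

    if "reproducibility" in cfg and som is not None and matrix is not None:
        @stage("reproducibility")
        def _():
            params = cfg["reproducibility"] or {}
            n_alt = int(params.get("n_alternates", 3))
            alts = []
            for i in range(n_alt):
                alt_cfg = som_mod.SomConfig(**{**som.config.to_dict(),
                                               "seed": config.seed + 1000 + i})
                alts.append(som_mod.train(matrix, alt_cfg))
            res = spa_mod.cocluster_reproducibility(
                som, alts, n_pairs=int(params.get("pairs", 10000)),
                near_radius=int(params.get("near", 5)), seed=config.seed)
            path = outdir / "reproducibility.tsv"
            with open(path, "w") as fh:
                fh.write(f"# {header}\n")
                fh.write("n_pairs\tn_same\tn_near\tfrac_same\tfrac_near\tnear_radius\n")
                fh.write(f"{res.n_pairs}\t{res.n_same}\t{res.n_near}"
                         f"\t{res.frac_same:.6g}\t{res.frac_near:.6g}\t{res.near_radius}\n")
            artifacts["reproducibility"] = path

    if "regions" in cfg and som is not None:
        @stage("regions")
        def _():
            path = outdir / "regions.tsv"
            with open(path, "w") as fh:
                fh.write(f"# {header}\n")
                fh.write("spec\tx\ty\n")
                for text in cfg["regions"]:
                    spec = reg_mod.parse_region_spec(text)
                    for x, y in sorted(reg_mod.select_nodes(som, spec),
                                       key=lambda xy: (xy[1], xy[0])):
                        fh.write(f"{text}\t{x}\t{y}\n")
            artifacts["regions"] = path

    if "overlay" in cfg and som is not None:
        @stage("overlay")
        def _():
            params = cfg["overlay"] or {}
            sets = io_formats.read_gene_sets(
                _require_path(params["sets"], "overlay gene sets"),
                params.get("dialect", "gmt"))
            df = reg_mod.overlay_counts(som, sets)
            path = outdir / "overlay.tsv"
            with open(path, "w") as fh:
                fh.write(f"# {header}\n")
                df.to_csv(fh, sep="\t", index=False)
            artifacts["overlay"] = path

    if not artifacts:
        raise ExprMapError("no stages configured (or stages missing their inputs)")
    return artifacts
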