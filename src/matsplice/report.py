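"""Run configuration and the consolidated per-gene report pipeline.

The pipeline ties the stages together in the order the analysis runs:
occurrence screening, splice/truncation analysis of transcripts against the
gene model, protein composition, and windowed propensity profiles.  Outputs
are deterministic for fixed inputs and configuration; every stage writes its
own TSV/JSON next to a Markdown summary, and a stage failure is recorded in
the summary without aborting the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

log = logging.getLogger("matsplice")

_LIST_KEYS = {"subjects", "stages"}
_INT_KEYS = {"window"}
_FLOAT_KEYS = {"edge_weight", "identity_threshold", "coverage_threshold",
               "identity_floor"}


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through the plain
    key=value config format."""

    stages: list[str] = field(default_factory=lambda: [
        "occurrence", "splice", "composition", "protscale",
    ])
    queries: str = ""
    subjects: list[str] = field(default_factory=list)
    gene: str = ""
    model: str = ""
    transcripts: str = ""
    proteins: str = ""
    scheme: str = ""
    scale: str = "helix"
    window: int = 21
    edge_weight: float = 1.0
    identity_threshold: float = 90.0
    coverage_threshold: float = 80.0
    identity_floor: float = 80.0
    out_prefix: str = "matsplice_out"
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and positive")
        if not 0 < self.edge_weight <= 1:
            raise ValueError("edge_weight must lie in (0, 1]")
        for name in ("identity_threshold", "coverage_threshold",
                     "identity_floor"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in _LIST_KEYS:
                kwargs[key] = [v for v in value.split(",") if v]
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key in _FLOAT_KEYS:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, list):
                value = ",".join(value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the report bundle dict.

    Output files are written under ``config.out_prefix``; the bundle mirrors
    what lands in ``summary.md``.
    """
    from . import composition as comp
    from . import occurrence as occ
    from . import protscale as ps
    from .seqcore import read_fasta
    from .splice import (
        classify_introns,
        SpliceParams,
        read_gene_model_gff3,
        read_gene_model_tsv,
    )

    outdir = Path(config.out_prefix)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"stages": {}, "config": asdict(config)}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            bundle["stages"][name] = {"status": "ok", "result": fn()}
            log.info("stage %s: ok", name)
        except Exception as exc:  # stage isolation is deliberate
            log.error("stage %s failed: %s", name, exc)
            bundle["stages"][name] = {"status": "failed", "error": str(exc)}

    def stage_occurrence():
        queries = read_fasta(config.queries)
        subjects = {
            Path(p).stem: read_fasta(p) for p in config.subjects
        }
        params = occ.OccurrenceParams(
            identity_threshold=config.identity_threshold,
            coverage_threshold=config.coverage_threshold,
        )
        matrix = occ.occurrence_matrix(queries, subjects, params)
        matrix.to_tsv(outdir / "occurrence.tsv")
        matrix.to_json(outdir / "occurrence.json")
        return {
            "n_subjects": len(matrix.subjects),
            "n_queries": len(matrix.queries),
            "absences": sum(
                1 for c in matrix.calls.values() if not c.present
            ),
        }

    def stage_splice():
        gene = read_fasta(config.gene)[0]
        model_path = Path(config.model)
        if model_path.suffix in (".gff", ".gff3"):
            model = read_gene_model_gff3(model_path, gene)
        else:
            model = read_gene_model_tsv(model_path, gene)
        params = SpliceParams(identity_floor=config.identity_floor)
        results = {}
        for tr in read_fasta(config.transcripts):
            report = classify_introns(model, tr, params)
            report.to_json(outdir / f"splice_{tr.id}.json")
            report.to_tsv(outdir / f"splice_{tr.id}.tsv")
            results[tr.id] = {
                "introns": [s.status for s in report.intron_statuses],
                "class": report.prediction.clazz if report.prediction else None,
                "product_length": (
                    len(report.prediction.product) if report.prediction else 0
                ),
            }
        return results

    def stage_composition():
        scheme = (
            comp.ResidueClassScheme.from_file(config.scheme)
            if config.scheme else comp.default_scheme()
        )
        profiles = [
            comp.composition_profile(p, scheme)
            for p in read_fasta(config.proteins, alphabet="protein")
        ]
        comp.profiles_to_tsv(profiles, outdir / "composition.tsv")
        return {
            p.protein_id: p.percentages for p in profiles
        }

    def stage_protscale():
        scale = ps.load_scale(config.scale)
        weights = ps.window_weights(config.window, config.edge_weight)
        out = {}
        for p in read_fasta(config.proteins, alphabet="protein"):
            profile = ps.windowed_profile(p, scale, weights)
            profile.to_tsv(outdir / f"protscale_{p.id}_{scale.name}.tsv")
            out[p.id] = {"n_positions": len(profile.positions)}
        return out

    run_stage("occurrence", stage_occurrence)
    run_stage("splice", stage_splice)
    run_stage("composition", stage_composition)
    run_stage("protscale", stage_protscale)

    (outdir / "report.json").write_text(json.dumps(bundle, indent=2) + "\n")
    _write_summary(bundle, outdir / "summary.md")
    return bundle


def _write_summary(bundle: dict, path: Path) -> None:
    lines = ["# matsplice report", ""]
    for name, info in bundle["stages"].items():
        lines.append(f"## {name}")
        lines.append("")
        if info["status"] != "ok":
            lines.append(f"**FAILED**: {info['error']}")
        else:
            lines.append("```json")
            lines.append(json.dumps(info["result"], indent=2))
            lines.append("```")
        lines.append("")
    path.write_text("\n".join(lines))
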