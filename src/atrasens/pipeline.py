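"""End-to-end orchestration: score -> signature -> predict (+ subtype, consensus).

A :class:`PipelineConfig` (loadable from YAML) names the input files and
stage parameters.  :func:`run_pipeline` validates the config up front,
runs the stages in a fixed order, writes per-stage outputs plus a JSON run
report (parameters, per-stage record counts), and is byte-reproducible
for identical config and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as aio
from .consensus import DEFAULT_FDR_MAX, common_sets, cross_group_overlap
from .dose_response import DEFAULT_DAY, DEFAULT_THRESHOLD, AtraScorer
from .enrichment import DEFAULT_ALPHA, predict_atra_scores, similarity_scores
from .signature import (DEFAULT_MIN_DEGREE, DEFAULT_P_MAX, DEFAULT_RHO_MIN,
                        derive_signature)
from .subtype import DEFAULT_N_PERM, ntp_classify, ntp_cross_validate

logger = logging.getLogger("atrasens")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run.

    ``growth``, ``expression`` and ``graph`` drive the mandatory
    score/signature/predict stages; ``cohort_expression`` defaults to
    ``expression``.  ``subtype_expression``+``template`` and ``manifest``
    switch on the optional subtype and consensus stages.
    """

    growth: Path
    expression: Path
    graph: Path
    outdir: Path
    cohort_expression: Path | None = None
    subtype_expression: Path | None = None
    template: Path | None = None
    manifest: Path | None = None
    day: int = DEFAULT_DAY
    threshold: float = DEFAULT_THRESHOLD
    p_max: float = DEFAULT_P_MAX
    rho_min: float = DEFAULT_RHO_MIN
    min_degree: int = DEFAULT_MIN_DEGREE
    alpha: float = DEFAULT_ALPHA
    fdr_max: float = DEFAULT_FDR_MAX
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("growth", "expression", "graph", "outdir"):
            if key not in doc:
                raise ValueError(f"config missing required key {key!r}")
        paths = {"growth", "expression", "graph", "outdir", "cohort_expression",
                 "subtype_expression", "template", "manifest"}
        kwargs = {k: (path.parent / v if k in paths and not Path(v).is_absolute() else v)
                  if k in paths else v
                  for k, v in doc.items()}
        return cls(**kwargs)

    def validate(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.rho_min < 0 or self.rho_min >= 1:
            raise ValueError("rho_min must be in [0, 1)")
        if self.min_degree < 0 or self.n_perm < 1:
            raise ValueError("min_degree must be >=0 and n_perm >=1")
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")
        for key in ("growth", "expression", "graph", "cohort_expression",
                    "subtype_expression", "template", "manifest"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} input not found: {p}")
        if (self.subtype_expression is None) != (self.template is None):
            raise ValueError("subtype stage needs both subtype_expression and template")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages in order and return the run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {k: (str(v) if isinstance(v, Path) else v)
                       for k, v in dataclasses.asdict(cfg).items()},
        "stages": {},
    }

    def _stage(name):
        logger.info("stage %s", name)
        return report["stages"].setdefault(name, {})

    try:
        rec = _stage("score")
        growth = aio.read_growth_table(cfg.growth)
        scorer = AtraScorer(day=cfg.day, threshold=cfg.threshold).fit(growth)
        aio.write_score_table(scorer.score_table_, outdir / "scores.tsv")
        rec.update(n_lines=len(scorer.score_table_),
                   n_high=int((scorer.score_table_["call"] == "high").sum()))

        rec = _stage("signature")
        expr = aio.read_expression(cfg.expression)
        graph = aio.read_interaction_graph(cfg.graph)
        scores = scorer.score_table_.set_index("cell_line")["atra_score"]
        sig = derive_signature(expr, scores, graph, p_max=cfg.p_max,
                               rho_min=cfg.rho_min, min_degree=cfg.min_degree)
        aio.write_signature(sig, outdir / "signature.gmt", outdir / "signature_detail.tsv")
        rec.update(n_direct=len(sig.direct), n_inverse=len(sig.inverse), meta=sig.meta)

        rec = _stage("predict")
        cohort = (aio.read_expression(cfg.cohort_expression)
                  if cfg.cohort_expression else expr)
        sim = similarity_scores(cohort, sig, alpha=cfg.alpha)
        pred = predict_atra_scores(sim, threshold=cfg.threshold)
        aio.write_enrichment_table(pred, outdir / "predictions.tsv")
        rec.update(n_samples=len(pred), n_high=int((pred["call"] == "high").sum()))

        if cfg.subtype_expression is not None:
            rec = _stage("subtype")
            sub_expr = aio.read_expression(cfg.subtype_expression)
            template = aio.read_template(cfg.template)
            calls = ntp_classify(sub_expr, template)
            aio.write_subtype_calls(calls, outdir / "subtype_calls.tsv")
            cv = ntp_cross_validate(sub_expr, template, n_perm=cfg.n_perm, seed=cfg.seed)
            (outdir / "subtype_cv.tsv").write_text(
                "permutation\taccuracy\n"
                + "".join(f"{i + 1}\t{a}\n" for i, a in enumerate(cv.accuracies))
            )
            rec.update(n_samples=len(calls), mean_cv_accuracy=cv.mean_accuracy,
                       sd_cv_accuracy=cv.sd_accuracy)

        if cfg.manifest is not None:
            rec = _stage("consensus")
            groups = aio.read_manifest(cfg.manifest)
            consensus = {}
            for name, files in groups.items():
                tables = {f.stem: aio.read_de_table(f) for f in files}
                consensus[name] = common_sets(tables, fdr_max=cfg.fdr_max, group=name)
            sets = {}
            for name, cs in consensus.items():
                sets[f"{name}_UP"] = sorted(cs.common_up)
                sets[f"{name}_DOWN"] = sorted(cs.common_down)
            aio.write_gmt(sets, outdir / "consensus.gmt")
            rec.update({name: {"n_up": len(cs.common_up), "n_down": len(cs.common_down)}
                        for name, cs in consensus.items()})
            names = list(consensus)
            if len(names) >= 2:
                shared_up, shared_down = cross_group_overlap(consensus[names[0]],
                                                             consensus[names[1]])
                rec["overlap_first_two"] = {"n_up": len(shared_up), "n_down": len(shared_down)}
    except Exception as exc:
        stage = next(reversed(report["stages"]), "setup")
        report["status"] = "error"
        report["failed_stage"] = stage
        report["error"] = str(exc)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report["status"] = "ok"
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
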