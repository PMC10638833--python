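"""Synthetic study data with known ground truth for every pipeline stage.

The generators emulate the five input kinds the pipeline consumes:

* Hill-curve growth panels (27 cell lines, ATRA 0.001-10 µM, days 3/6/9,
  10 replicate cultures per point) with analytically known noiseless AUCs;
* basal log2-CPM expression matrices with planted score-correlated genes
  (direct and inverse arms);
* gene-interaction graphs in which the planted signature genes form a
  connected cluster (clique by default) over sparse background edges;
* two-class subtype cohorts with a 171-gene template and mean-shifted
  class profiles;
* per-line differential-expression tables with planted consensus genes.

Every generator is deterministic given the config seed; each draws from
its own RNG stream derived from that seed, so the outputs of one stage do
not depend on whether another was generated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .subtype import SubtypeTemplate

_STREAM = {"growth": 1, "expression": 2, "graph": 3, "subtype": 4, "de": 5}


@dataclass
class SimulationConfig:
    """All tunable knobs of the synthetic study, with field-realistic defaults.

    Defaults mirror the study design the pipeline targets: a 27-line panel
    dosed 0.001-10 µM, a 1,000-gene background with a 30-gene planted
    signature (20 direct / 10 inverse) whose per-gene Spearman with the
    scores is ~0.8, a 171-gene two-class subtype template with a 3-SD
    class shift, and DE tables whose planted consensus genes are
    significant (FDR well below 0.1) in every line.
    """

    seed: int
    # growth panel
    n_lines: int = 27
    dose_grid_uM: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0)
    days: tuple[int, ...] = (3, 6, 9)
    replicates: int = 10
    noise_sd_growth: float = 5.0  # percent of the noiseless viability
    hill_params: list[tuple[float, float, float]] | None = None  # (EC50 µM, h, Emax %)
    # expression panel
    n_genes: int = 1000
    n_direct: int = 20
    n_inverse: int = 10
    effect_size: float = 5.0  # log2-CPM shift per unit ATRA-score
    noise_sd_expr: float = 1.0  # log2 CPM
    # interaction graph
    graph_background_p: float = 0.01
    cluster_style: str = "clique"  # or "cycle"
    # subtype cohort
    template_size: int = 171
    class_shift: float = 3.0  # in SD units
    n_samples_per_class: int = 30
    subtype_background_genes: int = 100
    # DE tables
    n_de_tables: int = 3
    de_n_genes: int = 500
    planted_common_up: tuple[str, ...] = tuple(f"CUP{i:02d}" for i in range(1, 13))
    planted_common_down: tuple[str, ...] = tuple(f"CDN{i:02d}" for i in range(1, 10))
    per_line_extra_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_lines", "replicates", "n_genes", "template_size",
                     "n_samples_per_class", "n_de_tables", "de_n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.graph_background_p <= 1:
            raise ValueError("graph_background_p must be in [0, 1]")
        if not 0 <= self.per_line_extra_rate <= 1:
            raise ValueError("per_line_extra_rate must be in [0, 1]")
        if self.n_direct + self.n_inverse >= self.n_genes:
            raise ValueError("planted signature must be smaller than the gene universe")
        if self.cluster_style not in ("clique", "cycle"):
            raise ValueError("cluster_style must be 'clique' or 'cycle'")
        if len(self.dose_grid_uM) < 2 or any(c <= 0 for c in self.dose_grid_uM):
            raise ValueError("dose grid needs >=2 strictly positive concentrations")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STREAM[stage], self.seed])


def _hill_response(conc: np.ndarray, ec50: float, h: float, emax: float) -> np.ndarray:
    """Fractional growth relative to vehicle under a Hill inhibition model."""
    return 1.0 - (emax / 100.0) * conc**h / (ec50**h + conc**h)


def _true_auc(ec50: float, h: float, emax: float, grid: tuple[float, ...],
              n_fine: int = 10_000) -> float:
    """Fine-grid trapezoid of the noiseless response (in %) over log10 dose."""
    lo, hi = np.log10(min(grid)), np.log10(max(grid))
    x = np.linspace(lo, hi, n_fine)
    return float(np.trapezoid(100.0 * _hill_response(10.0**x, ec50, h, emax), x))


def simulate_growth_panel(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Long-format growth table plus ground-truth Hill parameters and AUCs.

    Viability(c) = baseline * hill(c) * (1 + eps), eps ~ N(0, noise_sd/100);
    day-dependent efficacy ramps with exposure time (full effect at day 6).
    The true AUC is the fine-grid integral of the noiseless day-6 curve.
    """
    rng = cfg.rng("growth")
    lines = [f"LINE{i:02d}" for i in range(1, cfg.n_lines + 1)]
    if cfg.hill_params is not None:
        if len(cfg.hill_params) != cfg.n_lines:
            raise ValueError("hill_params must have one (EC50, h, Emax) per line")
        params = [tuple(map(float, p)) for p in cfg.hill_params]
    else:
        ec50 = 10.0 ** rng.uniform(-2.5, 1.5, cfg.n_lines)
        h = rng.uniform(0.8, 1.5, cfg.n_lines)
        emax = rng.uniform(20.0, 95.0, cfg.n_lines)
        params = list(zip(ec50, h, emax))
    for ec50_i, h_i, emax_i in params:
        if ec50_i <= 0 or h_i <= 0 or not 0 <= emax_i <= 100:
            raise ValueError(f"invalid Hill parameters ({ec50_i}, {h_i}, {emax_i})")

    conc = np.array([0.0, *cfg.dose_grid_uM])
    rows = []
    for line, (ec50_i, h_i, emax_i) in zip(lines, params):
        baseline = rng.uniform(0.5, 1.5)
        for day in cfg.days:
            day_eff = min(1.15, day / 6.0) if day >= 6 else day / 6.0
            resp = _hill_response(conc, ec50_i, h_i, min(100.0, emax_i * day_eff))
            resp[conc == 0] = 1.0
            for ci, r in zip(conc, resp):
                eps = rng.normal(0.0, cfg.noise_sd_growth / 100.0, cfg.replicates)
                for rep, e in enumerate(eps, start=1):
                    rows.append((line, ci, day, rep, max(0.0, baseline * r * (1.0 + e))))
    growth = pd.DataFrame(rows, columns=["cell_line", "concentration_uM", "day",
                                         "replicate", "viability"])
    truth = {
        "hill_params": {l: {"ec50_uM": p[0], "h": p[1], "emax_pct": p[2]}
                        for l, p in zip(lines, params)},
        "true_auc": {l: _true_auc(*p, cfg.dose_grid_uM) for l, p in zip(lines, params)},
    }
    return growth, truth


def _rescale(values: dict[str, float]) -> dict[str, float]:
    a = np.array(list(values.values()))
    span = a.max() - a.min()
    return {k: float((a.max() - v) / span) for k, v in values.items()}


def simulate_expression_panel(
    cfg: SimulationConfig, scores: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """Basal expression matrix with planted score-correlated signature genes.

    Background genes are N(mu_g, noise_sd_expr) with gene-specific means;
    direct genes add ``+effect_size * score`` and inverse genes
    ``-effect_size * score`` on the log2-CPM scale.
    """
    rng = cfg.rng("expression")
    samples = list(scores.index)
    direct = [f"DIR{i:02d}" for i in range(1, cfg.n_direct + 1)]
    inverse = [f"INV{i:02d}" for i in range(1, cfg.n_inverse + 1)]
    n_bg = cfg.n_genes - cfg.n_direct - cfg.n_inverse
    background = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    genes = direct + inverse + background
    mu = rng.uniform(2.0, 8.0, len(genes))
    X = mu[:, None] + rng.normal(0.0, cfg.noise_sd_expr, (len(genes), len(samples)))
    s = scores.to_numpy(dtype=float)
    X[: cfg.n_direct] += cfg.effect_size * s[None, :]
    X[cfg.n_direct : cfg.n_direct + cfg.n_inverse] -= cfg.effect_size * s[None, :]
    expr = pd.DataFrame(X, index=genes, columns=samples)
    truth = {"direct": direct, "inverse": inverse}
    return expr, truth


def simulate_interaction_graph(
    cfg: SimulationConfig, signature_genes: list[str], all_genes: list[str] | None = None
) -> nx.Graph:
    """Interaction graph with the signature wired as a connected cluster.

    ``cluster_style="clique"`` joins every signature pair; ``"cycle"``
    gives each signature gene degree exactly 2.  Every other unordered
    pair is edged independently with probability ``graph_background_p``.
    """
    rng = cfg.rng("graph")
    if all_genes is None:
        n_bg = cfg.n_genes - len(signature_genes)
        all_genes = list(signature_genes) + [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    sig = set(signature_genes)
    if not sig.issubset(all_genes):
        raise ValueError("signature genes must be contained in the gene universe")
    g = nx.Graph()
    g.add_nodes_from(all_genes)
    if len(signature_genes) >= 2:
        if cfg.cluster_style == "clique":
            g.add_edges_from(
                (a, b) for i, a in enumerate(signature_genes)
                for b in signature_genes[i + 1:]
            )
        else:  # cycle
            if len(signature_genes) < 3:
                raise ValueError("a cycle cluster needs >=3 signature genes")
            g.add_edges_from(zip(signature_genes, signature_genes[1:]))
            g.add_edge(signature_genes[-1], signature_genes[0])
    if cfg.graph_background_p > 0:
        nodes = np.array(all_genes, dtype=object)
        n = len(nodes)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < cfg.graph_background_p
        for a, b in zip(nodes[iu[mask]], nodes[ju[mask]]):
            if not (a in sig and b in sig):
                g.add_edge(a, b)
    return g


def simulate_subtype_cohort(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, SubtypeTemplate, pd.Series]:
    """Two-class cohort with a mean-shifted subtype template.

    Template genes split between classes G-INT and G-DIFF; a sample of
    class k is shifted ``+class_shift`` SD on class-k genes and
    ``-class_shift`` SD on the other class's template genes.
    """
    rng = cfg.rng("subtype")
    n_a = cfg.template_size // 2
    genes_a = [f"TA{i:03d}" for i in range(1, n_a + 1)]
    genes_b = [f"TB{i:03d}" for i in range(1, cfg.template_size - n_a + 1)]
    template = SubtypeTemplate({**{g: "G-INT" for g in genes_a},
                                **{g: "G-DIFF" for g in genes_b}})
    background = [f"SBG{i:03d}" for i in range(1, cfg.subtype_background_genes + 1)]
    genes = genes_a + genes_b + background
    labels = ["G-INT"] * cfg.n_samples_per_class + ["G-DIFF"] * cfg.n_samples_per_class
    samples = [f"S{i:03d}" for i in range(1, len(labels) + 1)]
    mu = rng.uniform(2.0, 8.0, len(genes))
    X = mu[:, None] + rng.normal(0.0, 1.0, (len(genes), len(samples)))
    sign_a = np.array([1.0 if lab == "G-INT" else -1.0 for lab in labels])
    X[: len(genes_a)] += cfg.class_shift * sign_a[None, :]
    X[len(genes_a): len(genes_a) + len(genes_b)] -= cfg.class_shift * sign_a[None, :]
    expr = pd.DataFrame(X, index=genes, columns=samples)
    return expr, template, pd.Series(labels, index=samples, name="subtype")


def simulate_de_tables(cfg: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-line DE tables with planted consensus genes.

    Planted common genes are significant (fdr ~ U(0, 0.05)) with a
    direction-consistent log2fc in every line; each line additionally
    gains ``per_line_extra_rate`` of the background as line-specific
    significant genes; everything else has fdr ~ U(0.2, 1), leaving a gap
    at the 0.1 threshold.
    """
    rng = cfg.rng("de")
    planted_up = list(cfg.planted_common_up)
    planted_down = list(cfg.planted_common_down)
    background = [f"G{i:04d}" for i in range(1, cfg.de_n_genes + 1)]
    genes = planted_up + planted_down + background
    tables: dict[str, pd.DataFrame] = {}
    for i in range(1, cfg.n_de_tables + 1):
        fdr = rng.uniform(0.2, 1.0, len(genes))
        log2fc = rng.normal(0.0, 1.0, len(genes))
        n_up, n_down = len(planted_up), len(planted_down)
        fdr[: n_up + n_down] = rng.uniform(0.0, 0.05, n_up + n_down)
        log2fc[:n_up] = np.abs(rng.normal(2.0, 0.5, n_up))
        log2fc[n_up : n_up + n_down] = -np.abs(rng.normal(2.0, 0.5, n_down))
        n_extra = int(round(cfg.per_line_extra_rate * len(background)))
        if n_extra:
            extra = n_up + n_down + rng.choice(len(background), n_extra, replace=False)
            fdr[extra] = rng.uniform(0.0, 0.05, n_extra)
            log2fc[extra] = rng.normal(0.0, 2.0, n_extra)
            log2fc[extra[log2fc[extra] == 0]] = 1.0
        tables[f"DELINE{i}"] = pd.DataFrame({"gene": genes, "log2fc": log2fc, "fdr": fdr})
    return tables


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Emit all five input kinds plus ``ground_truth.json`` into ``outdir``.

    Returns the ground-truth dictionary.  Files round-trip through the
    readers in :mod:`atrasens.io`.
    """
    from . import io as aio
    from .dose_response import AtraScorer

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    growth, growth_truth = simulate_growth_panel(cfg)
    aio.write_growth_table(growth, outdir / "growth.tsv")
    true_scores = _rescale(growth_truth["true_auc"])

    scorer = AtraScorer().fit(growth)
    scores = scorer.score_table_.set_index("cell_line")["atra_score"]
    expr, sig_truth = simulate_expression_panel(cfg, scores)
    aio.write_expression(expr, outdir / "expression.tsv")
    graph = simulate_interaction_graph(cfg, sig_truth["direct"] + sig_truth["inverse"],
                                       all_genes=list(expr.index))
    aio.write_interaction_graph(graph, outdir / "interactions.tsv")

    sub_expr, template, labels = simulate_subtype_cohort(cfg)
    aio.write_expression(sub_expr, outdir / "subtype_expression.tsv")
    aio.write_template(template, outdir / "subtype_template.tsv")

    de = simulate_de_tables(cfg)
    for name, table in de.items():
        aio.write_de_table(table, outdir / f"de_{name}.tsv")
    manifest = {"groups": {"simulated": [f"de_{name}.tsv" for name in de]}}
    aio.write_manifest(manifest, outdir / "groups.yaml")

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "true_auc": growth_truth["true_auc"],
        "hill_params": growth_truth["hill_params"],
        "true_scores": true_scores,
        "signature": sig_truth,
        "subtype_labels": labels.to_dict(),
        "planted_common_up": list(cfg.planted_common_up),
        "planted_common_down": list(cfg.planted_common_down),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
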