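"""End-to-end orchestration of the questionnaire network analysis.

A single :class:`PipelineConfig` (serialisable to YAML/JSON) drives the full
sequence: score → median split → per-group {correlation → network → summary
→ centrality → predictability → bootstrap → stability → embedding} →
two-group comparison.  Every artefact is written under the output directory
and listed, with a SHA-256 checksum, in ``manifest.json``; re-running an
identical config with the same master seed reproduces identical checksums.
The master seed spawns one child seed per stage through
``numpy.random.SeedSequence`` so partial re-runs stay consistent.
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

from . import cohort as cohort_mod
from .association import correlation_matrix
from .comparison import network_comparison_test
from .embedding import corr_to_dissimilarity, fr_layout, ordinal_mds
from .ggm import EstimationConfig, estimate_network, network_summary
from .metrics import centrality_indices, node_predictability, predictability_summary
from .resampling import bootstrap_edges, case_drop_stability, cs_coefficient
from .shsq import LikertResponseMatrix, load_responses, median_split, shs_scores

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("shsnet.pipeline")

_STAGE_NAMES = (
    "simulate", "score", "estimate", "accuracy", "stability", "compare", "embed",
)


@dataclass
class PipelineConfig:
    """Fully serialisable description of one pipeline run."""

    output_dir: str = "results/pipeline"
    input_csv: str | None = None  # if None, synthetic cohorts are generated
    synthetic: dict = field(
        default_factory=lambda: {
            "n_optimal": 106,
            "n_suboptimal": 111,
            "truth_density": 0.19,
            "weight_range": [0.15, 0.35],
        }
    )
    correlation_method: str = "polychoric"
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    bootstrap_B: int = 500
    stability_B_per_level: int = 50
    stability_proportions: list | None = None  # None = default 0.05..0.75 grid
    n_perm: int = 1000
    embedding_signed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.estimation, dict):
            self.estimation = EstimationConfig(**self.estimation)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


def _load_or_simulate(config: PipelineConfig, seeds: dict[str, int], outdir: Path,
                      artefacts: dict) -> dict[str, LikertResponseMatrix]:
    if config.input_csv is not None:
        log.info("loading responses from %s", config.input_csv)
        m = load_responses(config.input_csv)
        scores = median_split(shs_scores(m))
        groups = {}
        for label in ("optimal", "suboptimal"):
            idx = scores.status_label == label
            groups[label] = LikertResponseMatrix(
                respondent_ids=[r for r, k in zip(m.respondent_ids, idx) if k],
                items=m.items,
                ratings=m.ratings[np.asarray(idx)],
                domain_map=m.domain_map,
            )
        return groups
    syn = config.synthetic
    log.info("simulating cohorts: %s", syn)
    truth = cohort_mod.make_truth_network(
        p=25,
        density=syn.get("truth_density", 0.19),
        weight_range=tuple(syn.get("weight_range", (0.15, 0.35))),
        seed=seeds["simulate"],
    )
    groups = {}
    for i, (label, n_key) in enumerate(
        [("optimal", "n_optimal"), ("suboptimal", "n_suboptimal")]
    ):
        preset = cohort_mod.preset(f"{label}_like", n=syn.get(n_key))
        groups[label] = cohort_mod.generate_cohort(truth, preset, seed=seeds["simulate"] + i + 1)
        path = outdir / f"cohort_{label}.csv"
        groups[label].to_csv(path)
        artefacts[f"cohort_{label}"] = path
    return groups


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the manifest dict.

    Any stage failure aborts with a stage-tagged error; artefacts written
    before the failure stay on disk and the manifest is saved with
    ``complete: false``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artefacts: dict[str, Path] = {}
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "complete": False,
        "artifacts": {},
    }
    config.to_file(outdir / "config.yaml")
    artefacts["config"] = outdir / "config.yaml"

    stage = "simulate"
    try:
        groups = _load_or_simulate(config, seeds, outdir, artefacts)

        stage = "score"
        for label, m in groups.items():
            st = shs_scores(m)
            path = outdir / f"scores_{label}.csv"
            st.to_frame().to_csv(path, index_label="respondent_id")
            artefacts[f"scores_{label}"] = path

        stage = "estimate"
        nets, corrs = {}, {}
        for label, m in groups.items():
            S = correlation_matrix(m, method=config.correlation_method)
            corrs[label] = S
            net = estimate_network(S, n=m.n_respondents, config=config.estimation)
            nets[label] = net
            S.to_frame().to_csv(outdir / f"correlation_{label}.csv")
            artefacts[f"correlation_{label}"] = outdir / f"correlation_{label}.csv"
            net.edge_list().to_csv(outdir / f"edges_{label}.tsv", sep="\t", index=False)
            artefacts[f"edges_{label}"] = outdir / f"edges_{label}.tsv"
            pd.DataFrame(net.weights, index=net.labels, columns=net.labels).to_csv(
                outdir / f"weights_{label}.csv"
            )
            artefacts[f"weights_{label}"] = outdir / f"weights_{label}.csv"
            import networkx as nx

            nx.write_graphml(net.to_graph(), outdir / f"network_{label}.graphml")
            artefacts[f"network_{label}"] = outdir / f"network_{label}.graphml"
            summ = network_summary(net)
            cent = centrality_indices(net)
            pred = node_predictability(net, S)
            cent.values.join(cent.zscores, rsuffix="_z").to_csv(
                outdir / f"centrality_{label}.csv"
            )
            artefacts[f"centrality_{label}"] = outdir / f"centrality_{label}.csv"
            meta = {
                "lambda": net.lambda_,
                "ebic": net.ebic,
                "n": net.n,
                "edge_count": summ.edge_count,
                "density": summ.density,
                "mean_abs_nonzero_weight": summ.mean_abs_nonzero_weight,
                "mean_predictability": predictability_summary(pred),
                "predictability": pred.values.round(4).to_dict(),
            }
            (outdir / f"network_{label}.json").write_text(json.dumps(meta, indent=2))
            artefacts[f"network_meta_{label}"] = outdir / f"network_{label}.json"
            log.info("[estimate:%s] lambda=%.4f edges=%d density=%.3f",
                     label, net.lambda_, summ.edge_count, summ.density)

        stage = "accuracy"
        for label, m in groups.items():
            _, ci = bootstrap_edges(
                m, config.estimation, B=config.bootstrap_B,
                seed=seeds["accuracy"], method=config.correlation_method,
            )
            ci.to_csv(outdir / f"edge_ci_{label}.csv", index=False)
            artefacts[f"edge_ci_{label}"] = outdir / f"edge_ci_{label}.csv"

        stage = "stability"
        cs_all = {}
        for label, m in groups.items():
            res = case_drop_stability(
                m, config.estimation, B_per_level=config.stability_B_per_level,
                proportions=(
                    np.asarray(config.stability_proportions)
                    if config.stability_proportions is not None else None
                ),
                seed=seeds["stability"], method=config.correlation_method,
            )
            rows = []
            for k, mat in res.correlations.items():
                for qi, q in enumerate(res.proportions):
                    for b in range(mat.shape[1]):
                        rows.append((q, b, k, mat[qi, b]))
            pd.DataFrame(
                rows, columns=["proportion", "replicate", "index", "correlation"]
            ).to_csv(outdir / f"drop_curves_{label}.csv", index=False)
            artefacts[f"drop_curves_{label}"] = outdir / f"drop_curves_{label}.csv"
            cs_all[label] = cs_coefficient(res)
        (outdir / "cs_coefficients.json").write_text(json.dumps(cs_all, indent=2))
        artefacts["cs_coefficients"] = outdir / "cs_coefficients.json"

        stage = "compare"
        cmp_res = network_comparison_test(
            groups["optimal"], groups["suboptimal"], config.estimation,
            n_perm=config.n_perm, seed=seeds["compare"],
            method=config.correlation_method,
        )
        (outdir / "comparison.json").write_text(
            json.dumps(
                {
                    "observed": cmp_res.observed,
                    "p_values": cmp_res.p_values,
                    "global_strength": {
                        "optimal": cmp_res.global_strength_a,
                        "suboptimal": cmp_res.global_strength_b,
                    },
                    "adjacency_correlation": cmp_res.adjacency_corr,
                    "n_perm": cmp_res.n_perm,
                },
                indent=2,
            )
        )
        artefacts["comparison"] = outdir / "comparison.json"

        stage = "embed"
        for label in groups:
            D = corr_to_dissimilarity(corrs[label], signed=config.embedding_signed)
            emb = ordinal_mds(D, seed=seeds["embed"])
            pd.DataFrame(
                emb.coordinates, index=corrs[label].labels, columns=["x", "y"]
            ).to_csv(outdir / f"mds_{label}.csv", index_label="node")
            artefacts[f"mds_{label}"] = outdir / f"mds_{label}.csv"
            emb.shepard.to_csv(outdir / f"shepard_{label}.csv", index=False)
            artefacts[f"shepard_{label}"] = outdir / f"shepard_{label}.csv"
            fr = fr_layout(nets[label], seed=seeds["embed"])
            fr.to_csv(outdir / f"fr_layout_{label}.csv")
            artefacts[f"fr_layout_{label}"] = outdir / f"fr_layout_{label}.csv"

        manifest["complete"] = True
    except Exception as err:
        manifest["error"] = f"[stage {stage}] {err}"
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
    finally:
        manifest["artifacts"] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in artefacts.items()
            if Path(p).exists()
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
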