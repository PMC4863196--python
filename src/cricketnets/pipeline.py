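"""One-command orchestration of the full single-season analysis.

Stage order mirrors the analysis workflow: isolate filtering, network
construction, Mantel covariate checks (the rationale for semipartialling:
the spatial/temporal covariates are typically correlated with fighting),
symmetrization and predictor standardization, MRQAP of sperm competition
on fighting + space + time, node-level degree/strength comparisons, and
the bipartite degree-correlation test against its density-matched null.

All randomness flows from one top-level seed via a deterministic split,
so identical inputs and config produce a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from ._version import __version__
from .exceptions import CricketNetsError, PipelineStageError
from .network_build import (
    BipartiteMatrix,
    build_fighting_network,
    build_mating_bipartite,
    build_spatial_overlap,
    build_temporal_overlap,
    elementwise_product,
    filter_isolates,
    project_sperm_competition,
    standardize_offdiag,
    symmetrize_geometric,
)
from .node_stats import (
    NullDistributionResult,
    bipartite_degree_correlation,
    degree_correlation_null,
    degree_vector,
    paired_signed_rank,
    rank_correlation,
    strength_vector,
)
from .qap_stats import MRQAPResult, mantel_test, mrqap_dsp
from .records_io import ObservationSet

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    n_perm: int = 2000
    n_sim: int = 1000
    tail: Literal["upper", "two"] = "upper"
    dyad_set: Literal["unordered", "ordered"] = "unordered"
    statistic: Literal["t", "coef"] = "t"
    seed: int = 0
    label: str = "season"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisReport:
    label: str
    n_males_total: int
    n_males_retained: int
    n_females: int
    mantel: dict
    mrqap: MRQAPResult
    degree_comparison: dict
    within_individual: dict
    degree_correlation: NullDistributionResult
    provenance: dict

    def to_dict(self) -> dict:
        mr = self.mrqap
        dc = self.degree_correlation
        return {
            "label": self.label,
            "n_males_total": self.n_males_total,
            "n_males_retained": self.n_males_retained,
            "n_females": self.n_females,
            "mantel": self.mantel,
            "mrqap": {
                "predictor_names": list(mr.predictor_names),
                "coefficients": [float(c) for c in mr.coefficients],
                "permutation_p": [float(p) for p in mr.permutation_p],
                "t_values": [float(t) for t in mr.t_values],
                "intercept": float(mr.intercept),
                "r_squared": float(mr.r_squared),
                "residual_standard_error": float(mr.residual_standard_error),
                "degrees_of_freedom": int(mr.degrees_of_freedom),
                "n_permutations": int(mr.n_permutations),
                "seed": mr.seed,
                "method": mr.method,
                "statistic": mr.statistic,
            },
            "degree_comparison": self.degree_comparison,
            "within_individual": self.within_individual,
            "degree_correlation": {
                "observed": float(dc.observed),
                "p": float(dc.p),
                "n_sim": int(dc.n_sim),
                "seed": dc.seed,
                "tail": dc.tail,
                "n_redraws": int(dc.n_redraws),
                "simulated_quantiles": {
                    q: float(np.quantile(dc.simulated, float(q)))
                    for q in ("0.025", "0.25", "0.5", "0.75", "0.975")
                },
            },
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write report.json, a one-row-per-predictor MRQAP CSV and the
        null distribution CSV (one simulated correlation per row)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": out / "report.json",
            "mrqap_table": out / "mrqap_table.csv",
            "null_distribution": out / "null_distribution.csv",
        }
        paths["report"].write_text(self.to_json() + "\n")
        table = self.mrqap.to_table()
        table.insert(0, "label", self.label)
        table.to_csv(paths["mrqap_table"], index=False, lineterminator="\n")
        pd.DataFrame({"simulated_r": self.degree_correlation.simulated}).to_csv(
            paths["null_distribution"], index=False, lineterminator="\n"
        )
        return paths


def observation_checksum(obs: ObservationSet) -> str:
    """SHA-256 over a canonical serialization of the observation set."""
    payload = json.dumps(
        {
            "roster": [dataclasses.astuple(i) for i in obs.roster],
            "occupancy": [dataclasses.astuple(r) for r in obs.occupancy],
            "fights": [dataclasses.astuple(e) for e in obs.fights],
            "matings": [dataclasses.astuple(e) for e in obs.matings],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CricketNetsError) and not isinstance(
                exc, PipelineStageError
            ):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_full_analysis(obs: ObservationSet, config: AnalysisConfig) -> AnalysisReport:
    """Run the three-prediction workflow on one season of observations."""
    # deterministic seed split: one stream per randomized sub-analysis
    sub = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=8)
    seeds = {
        "mantel_fighting_space": int(sub[0]),
        "mantel_fighting_time": int(sub[1]),
        "mantel_space_time": int(sub[2]),
        "mrqap": int(sub[3]),
        "degree_correlation": int(sub[4]),
    }

    with _stage("isolate-filtering"):
        retained = filter_isolates(obs)
        males_all = obs.male_ids
        if len(retained) < 5:
            raise PipelineStageError(
                "isolate-filtering",
                f"only {len(retained)} non-isolated males; need >= 5",
            )

    with _stage("network-construction"):
        fighting = build_fighting_network(obs, retained)
        mating = build_mating_bipartite(obs, male_ids=retained)
        sperm = project_sperm_competition(mating)
        space = build_spatial_overlap(obs, retained)
        time_ov = build_temporal_overlap(obs, retained)

    with _stage("symmetrize-standardize"):
        fighting_sym = symmetrize_geometric(fighting)
        sperm_sym = symmetrize_geometric(sperm)
        predictors = {
            "fighting": standardize_offdiag(fighting_sym),
            "space": standardize_offdiag(space),
            "time": standardize_offdiag(time_ov),
        }

    with _stage("mantel-covariates"):
        mantel = {}
        pairs = [
            ("fighting", "space"), ("fighting", "time"), ("space", "time"),
        ]
        for a, b in pairs:
            res = mantel_test(
                predictors[a], predictors[b], n_perm=config.n_perm,
                seed=seeds[f"mantel_{a}_{b}"], dyad_set=config.dyad_set,
            )
            mantel[f"{a}~{b}"] = {
                "r": float(res.r), "p": float(res.p),
                "n_permutations": res.n_permutations,
            }

    with _stage("mrqap"):
        mr = mrqap_dsp(
            sperm_sym,
            [predictors["fighting"], predictors["space"], predictors["time"]],
            n_perm=config.n_perm,
            seed=seeds["mrqap"],
            predictor_names=["fighting", "space", "time"],
            statistic=config.statistic,
            dyad_set=config.dyad_set,
        )

    with _stage("degree-comparison"):
        deg_fight = degree_vector(fighting, "all")
        deg_sperm = degree_vector(sperm, "all")
        w_stat, w_p = paired_signed_rank(deg_fight, deg_sperm)
        degree_comparison = {
            "W": float(w_stat),
            "p": float(w_p),
            "n": len(retained),
            "median_fighting_degree": float(np.median(deg_fight.values)),
            "median_sperm_degree": float(np.median(deg_sperm.values)),
        }

    with _stage("within-individual"):
        rd, pd_ = rank_correlation(deg_fight, deg_sperm)
        sf = strength_vector(fighting)
        ss = strength_vector(sperm)
        rs, ps = rank_correlation(sf, ss)
        within_individual = {
            "degree": {"r_s": float(rd), "p": float(pd_)},
            "strength": {"r_s": float(rs), "p": float(ps)},
            "n": len(retained),
        }

    with _stage("degree-correlation"):
        females = obs.female_ids
        mixed_nodes = tuple(retained) + tuple(females)
        t_mixed = build_temporal_overlap(obs, mixed_nodes)
        s_mixed = build_spatial_overlap(obs, mixed_nodes)
        possible = elementwise_product(s_mixed, t_mixed)
        nm = len(retained)
        possibility = BipartiteMatrix(
            tuple(retained), tuple(females), possible.values[:nm, nm:]
        )
        dc = degree_correlation_null(
            mating, possibility, n_sim=config.n_sim,
            seed=seeds["degree_correlation"], tail=config.tail,
        )

    provenance = {
        "seed": config.seed,
        "sub_seeds": seeds,
        "config": config.to_dict(),
        "package_version": __version__,
        "input_checksum": observation_checksum(obs),
        "counts": {
            "n_males_total": len(males_all),
            "n_males_retained": len(retained),
            "n_isolates": len(males_all) - len(retained),
            "n_dyads": len(retained) * (len(retained) - 1) // 2,
            "n_mating_edges": len(mating.edges()),
            "n_possible_edges": int((possibility.values > 0).sum()),
        },
    }
    return AnalysisReport(
        label=config.label,
        n_males_total=len(males_all),
        n_males_retained=len(retained),
        n_females=len(obs.female_ids),
        mantel=mantel,
        mrqap=mr,
        degree_comparison=degree_comparison,
        within_individual=within_individual,
        degree_correlation=dc,
        provenance=provenance,
    )


def plot_null_distribution(result: NullDistributionResult, path: str | Path):
    """Basic quantile plot of the simulated degree correlations with the
    observed value marked (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    sims = np.sort(result.simulated)
    ax.violinplot([sims], positions=[0], showmedians=True)
    for q in (0.025, 0.25, 0.75, 0.975):
        ax.axhline(np.quantile(sims, q), ls="--", lw=0.6, color="gray")
    ax.plot([0], [result.observed], marker="*", ms=14, color="black",
            label=f"observed r = {result.observed:.3f}")
    ax.set_ylabel("degree correlation (Spearman r over edges)")
    ax.set_xticks([])
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
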