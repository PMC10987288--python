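"""End-to-end study orchestration.

``run_study`` wires the whole analysis together: simulate (or load) an
ASV-by-sample table, filter rare ASVs, source-track every gut community
against the water and sediment samples, classify habitat preference from the
coalescence extents, compute trophic groups from delta-15N, evaluate the four
candidate factors (habitat, species, family, trophic group) by ANOSIM with BH
FDR, PAM matching rate and random-forest AUC, build per-habitat co-occurrence
networks, and compare their robustness slopes. Everything is driven by one
seed; stage-level seeds are spawned deterministically from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .clusteval import ClusterEvaluation, matching_rate, select_k, supervised_auc
from .divstats import (
    anosim,
    bh_fdr,
    bray_curtis_matrix,
    nmds,
    shared_fraction,
    axis_group_test,
)
from .isotope import TrophicParams, trophic_table
from .netstab import build_network, robustness_slope
from .sourcetrack import track_study
from .synth import StudyConfig, generate_study
from .tables import (
    AbundanceTable,
    SampleMetadata,
    aggregate_by_class,
    filter_rare_asvs,
    metadata_by_id,
    read_metadata_tsv,
    relative_abundance,
)

FACTORS = ("habitat", "species", "family", "trophic_group")


class PipelineError(ValueError):
    """Raised for invalid pipeline configurations or inputs."""


@dataclass
class PipelineConfig:
    """Run-level options; ``simulate`` switches between synthetic and file input."""

    simulate: bool = True
    study: StudyConfig = field(default_factory=StudyConfig)
    abundance_path: str | None = None
    metadata_path: str | None = None
    filter_fraction: float = 5e-5
    anosim_permutations: int = 999
    k_range: tuple[int, int] = (2, 8)
    n_trees: int = 500
    rho_threshold: float = 0.8
    q_threshold: float = 0.05
    prevalence: float = 0.5
    robustness_iterations: int = 1000
    include_unknown: bool = True
    trophic: TrophicParams = field(default_factory=TrophicParams)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        study = StudyConfig(**raw.pop("study", {}))
        trophic = TrophicParams(**raw.pop("trophic", {}))
        return cls(study=study, trophic=trophic, **raw)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _config_hash(config: PipelineConfig, seed: int) -> str:
    blob = json.dumps(
        {"config": str(dataclasses.asdict(config)), "seed": seed}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_study(
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the full analysis; returns (and optionally writes) the study report.

    The report is a JSON-serializable dict with the coalescence/habitat table,
    the per-factor ANOSIM results (BH-adjusted across the four factors), the
    PAM cluster evaluation with per-factor matching rates, the per-factor
    AUCs, shared-ASV fractions, NMDS stress and axis-1 habitat p-value, and
    the per-habitat-group network robustness slopes.
    """
    if config is None:
        config = PipelineConfig()
    seeds = _stage_seeds(seed)

    truth = None
    if config.simulate:
        table, meta, truth = generate_study(config.study, seed=seeds[0])
    else:
        if not config.abundance_path or not config.metadata_path:
            raise PipelineError("abundance_path and metadata_path required when simulate=false")
        table = AbundanceTable.read_tsv(config.abundance_path)
        meta = read_metadata_tsv(config.metadata_path)
    lookup = metadata_by_id(meta)
    missing = [s for s in table.sample_ids if s not in lookup]
    if missing:
        raise PipelineError(f"samples without metadata: {missing}")

    table = filter_rare_asvs(table, config.filter_fraction)

    # --- coalescence / habitat preference -------------------------------
    _, coal = track_study(
        table, meta, include_unknown=config.include_unknown, seed=seeds[1]
    )
    gut_ids = list(coal.index)

    # --- trophic groups --------------------------------------------------
    delta = {s: lookup[s].delta15N for s in gut_ids}
    if any(v is None for v in delta.values()):
        raise PipelineError("trophic grouping requested but delta15N missing for gut samples")
    trophic_params = config.trophic
    if config.simulate:
        # the simulated study emits its own primary-consumer reference value
        trophic_params = dataclasses.replace(
            trophic_params, reference_delta15n=config.study.reference_delta15n
        )
    trophic = trophic_table(delta, trophic_params)

    factor_labels = {
        "habitat": coal["habitat"].to_numpy(),
        "species": np.array([lookup[s].species_code for s in gut_ids]),
        "family": np.array([lookup[s].family for s in gut_ids]),
        "trophic_group": trophic.loc[gut_ids, "trophic_group"].to_numpy(),
    }

    # --- diversity / factor statistics ----------------------------------
    gut = table.subset_samples(gut_ids)
    dist = bray_curtis_matrix(gut.counts, gut_ids)
    anosim_rows = []
    for fi, factor in enumerate(FACTORS):
        res = anosim(
            dist, factor_labels[factor],
            n_permutations=config.anosim_permutations, seed=seeds[2] + fi,
        )
        anosim_rows.append({"factor": factor, "R": res.r, "p": res.p})
    qvals = bh_fdr([row["p"] for row in anosim_rows])
    for row, q in zip(anosim_rows, qvals):
        row["q"] = float(q)

    ord_res = nmds(dist, seed=seeds[3])
    axis_p = axis_group_test(ord_res.coordinates[:, 0], factor_labels["habitat"])

    presence = aggregate_by_class(table, meta)
    shared = {
        cls: shared_fraction(presence[cls], presence["gut"])
        for cls in ("water", "sediment")
        if presence[cls]
    }

    # --- clustering and classification -----------------------------------
    evaluation = select_k(dist, range(config.k_range[0], config.k_range[1] + 1), seed=seeds[4])
    for factor in FACTORS:
        evaluation.matching_rates[factor] = matching_rate(
            evaluation.labels, factor_labels[factor]
        )
    features = relative_abundance(gut).T
    aucs = {}
    for fi, factor in enumerate(FACTORS):
        aucs[factor] = supervised_auc(
            features, factor_labels[factor], factor_name=factor,
            n_trees=config.n_trees, seed=seeds[5] + fi,
        ).macro_auc

    # --- per-habitat networks --------------------------------------------
    robustness = {}
    for gi, group in enumerate(("pelagic", "benthic")):
        members = [s for s, h in zip(gut_ids, factor_labels["habitat"]) if h == group]
        if len(members) < 5:
            robustness[group] = None
            continue
        net = build_network(
            table, members,
            rho_threshold=config.rho_threshold, q_threshold=config.q_threshold,
            prevalence=config.prevalence, group=group,
        )
        if net.graph.number_of_nodes() < 4:
            robustness[group] = None
            continue
        rob = robustness_slope(
            net, n_iterations=config.robustness_iterations, seed=seeds[6] + gi
        )
        robustness[group] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "slope": rob.slope,
            "intercept": rob.intercept,
            "fractions": rob.fractions.tolist(),
            "mean_connectivity": rob.mean_connectivity.tolist(),
        }

    report: dict[str, Any] = {
        "provenance": {
            "seed": seed,
            "config_hash": _config_hash(config, seed),
            "version": __version__,
        },
        "n_samples": {"gut": len(gut_ids), "total": table.n_samples},
        "n_taxa_after_filter": table.n_taxa,
        "coalescence": coal.reset_index().to_dict(orient="records"),
        "trophic": trophic.reset_index().to_dict(orient="records"),
        "anosim": anosim_rows,
        "nmds": {"stress": ord_res.stress, "axis1_habitat_p": float(axis_p)},
        "shared_fraction": shared,
        "clustering": {
            "k_values": evaluation.k_values,
            "ch_scores": evaluation.ch_scores,
            "silhouette_means": evaluation.silhouette_means,
            "selected_k": evaluation.selected_k,
            "matching_rates": evaluation.matching_rates,
        },
        "auc": aucs,
        "robustness": robustness,
    }
    if truth is not None:
        merged = coal.join(truth, rsuffix="_true")
        report["ground_truth_accuracy"] = {
            "habitat": float((merged["habitat"] == merged["habitat_true"]).mean()),
            "mae_alpha_water": float((merged["water_total"] - merged["alpha_water"]).abs().mean()),
            "mae_alpha_sediment": float(
                (merged["sediment_total"] - merged["alpha_sediment"]).abs().mean()
            ),
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        coal.to_csv(outdir / "coalescence.tsv", sep="\t")
        trophic.to_csv(outdir / "trophic.tsv", sep="\t")
        pd.DataFrame(anosim_rows).to_csv(outdir / "anosim.tsv", sep="\t", index=False)
    return report


def factor_ranking(report: Mapping[str, Any]) -> pd.DataFrame:
    """Per-factor ANOSIM R, matching rate and AUC, sorted by ANOSIM R."""
    rows = []
    for row in report["anosim"]:
        f = row["factor"]
        rows.append(
            {
                "factor": f,
                "anosim_R": row["R"],
                "anosim_q": row["q"],
                "matching_rate": report["clustering"]["matching_rates"][f],
                "auc": report["auc"][f],
            }
        )
    return pd.DataFrame(rows).sort_values("anosim_R", ascending=False).reset_index(drop=True)
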