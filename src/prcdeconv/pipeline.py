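"""End-to-end pipeline: simulate/load -> filter -> deconvolve -> quantify -> score -> enrich.

Every stage writes its intermediate table under the output directory, and a
single ``summary.json`` collects all Venn region counts, concordance
counts, recovery metrics and overlap p-values, so each reported number can
be recomputed from the emitted tables.  A parameter echo goes to
``pipeline.log``.  The same configuration and seed reproduce the bundle
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .deconvolution import (
    assign_membership,
    chromatome_partition,
    compare_baits,
    intersect_lines,
    recovery_metrics,
)
from .errors import PipelineError
from .filtering import (
    ContaminantRepository,
    build_interactor_set,
    detect_in_mocks,
    filter_contaminants,
    read_intensity_table,
    subtract_mock,
)
from .modulation import quantify_modulation
from .overlap import deu_overlap_analysis, read_deu_table, read_gene_set
from .synthetic import (
    GroundTruth,
    default_config,
    repository_from_truth,
    simulate_interactome,
    write_fixture,
)


@dataclass
class PipelineConfig:
    """All pipeline inputs and stage parameters in one auditable object."""

    out_dir: str = "prcdeconv_out"
    seed: int = 0
    # inputs; when intensities is None the default synthetic screen is run
    intensities: str | None = None
    metadata: str | None = None
    ground_truth: str | None = None
    contaminant_repo: str | None = None
    deu_table: str | None = None
    gene_sets: dict = field(default_factory=dict)  # name -> path
    # design roles
    hub_bait: str = "BMI1"
    partner_bait: str = "RYBP"
    mark_bait: str = "H2AK119ub"
    up_line: str | None = None
    down_line: str | None = None
    set_condition: str = "control"
    # stage parameters
    min_runs: int = 2
    mock_min_runs: int = 1
    max_contaminant_freq: float = 0.10
    normalize: str = "none"
    pseudo: float = 1.0
    fc_min: float = 0.0
    alpha: float | None = None
    missing_policy: str = "impute_floor"
    floor: float = 1.0
    enrich_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown fields {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict it also writes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    log_lines = [f"parameters: {json.dumps(asdict(config), sort_keys=True)}"]

    # ---- load / simulate -------------------------------------------------
    stage = "load"
    try:
        truth = None
        if config.intensities is not None:
            if config.metadata is None:
                raise ValueError("metadata path required with intensities")
            matrix = read_intensity_table(config.intensities, config.metadata)
            if config.ground_truth is not None:
                truth = GroundTruth.from_tsv(config.ground_truth)
            lines = list(dict.fromkeys(matrix.samples["cell_line"]))
        else:
            sim = default_config(seed=config.seed)
            matrix, truth = simulate_interactome(sim)
            write_fixture(matrix, truth, out / "fixture")
            lines = list(sim.cell_lines)
        if len(lines) != 2:
            raise ValueError(f"expected exactly 2 cell lines, found {lines}")
        up_line = config.up_line or lines[0]
        down_line = config.down_line or lines[1]
        if config.contaminant_repo is not None:
            repo = ContaminantRepository.from_tsv(config.contaminant_repo)
        elif truth is not None:
            repo = repository_from_truth(truth)
            repo.to_tsv(out / "contaminant_repository.tsv")
        else:
            repo = ContaminantRepository(frequencies=pd.Series(dtype=float))
        baits = [
            b
            for b in dict.fromkeys(matrix.samples["bait"])
            if not (matrix.samples["bait"].eq(b) & matrix.samples["is_mock"].eq(1)).any()
        ]
        summary["design"] = {
            "cell_lines": lines,
            "baits": baits,
            "n_samples": int(len(matrix.samples)),
            "n_proteins": int(len(matrix.proteins)),
        }
        log_lines.append(
            f"load: {len(matrix.proteins)} proteins x {len(matrix.samples)} samples"
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(e)) from e

    # ---- filter ----------------------------------------------------------
    stage = "filter"
    try:
        isets = {}
        summary["filter"] = {}
        for bait in baits:
            for line in lines:
                s = build_interactor_set(
                    matrix, bait, line, config.set_condition, config.min_runs
                )
                mocks = detect_in_mocks(
                    matrix, line, config.set_condition, config.mock_min_runs
                )
                s = subtract_mock(s, mocks)
                s = filter_contaminants(s, repo, config.max_contaminant_freq)
                isets[(bait, line)] = s
                s.to_tsv(out / f"interactors.{bait}.{line}.tsv")
                summary["filter"][f"{bait}|{line}"] = {
                    "n_proteins": len(s),
                    "filters": [[n, r] for n, r in s.provenance],
                }
                log_lines.append(f"filter: {bait}/{line}: {len(s)} interactors")
        universe = frozenset().union(*(s.proteins for s in isets.values()))
        summary["universe_size"] = len(universe)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ---- deconvolve ------------------------------------------------------
    stage = "deconvolve"
    try:
        shared = {}
        summary["venn_lines"] = {}
        for bait in baits:
            rep = intersect_lines(isets[(bait, lines[0])], isets[(bait, lines[1])])
            shared[bait] = rep.region((lines[0], lines[1]))
            summary["venn_lines"][bait] = rep.counts()
        hub_s = shared.get(config.hub_bait, frozenset())
        partner_s = shared.get(config.partner_bait, frozenset())
        mark_s = shared.get(config.mark_bait, frozenset())
        bait_rep = compare_baits(
            hub_s, partner_s, labels=(config.hub_bait, config.partner_bait)
        )
        summary["venn_baits"] = bait_rep.counts()
        chrom_rep, _ = chromatome_partition(
            hub_s,
            partner_s,
            mark_s,
            labels=(config.hub_bait, config.partner_bait, config.mark_bait),
        )
        summary["venn_chromatome"] = chrom_rep.counts()
        assignment = assign_membership(hub_s, partner_s, mark_s, universe=universe)
        assignment.to_tsv(out / "membership.tsv")
        summary["membership_counts"] = assignment.counts()
        single_line = sorted(universe - frozenset().union(*shared.values()))
        summary["n_single_line_evidence"] = len(single_line)
        (out / "venn_reports.json").write_text(
            json.dumps(
                {
                    "lines": {b: summary["venn_lines"][b] for b in baits},
                    "baits": bait_rep.to_json_dict(),
                    "chromatome": chrom_rep.to_json_dict(),
                },
                indent=2,
                sort_keys=True,
            )
        )
        log_lines.append(
            "deconvolve: membership "
            + json.dumps(summary["membership_counts"], sort_keys=True)
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ---- quantify --------------------------------------------------------
    stage = "quantify"
    try:
        quant = quantify_modulation(
            matrix,
            hub_s,
            config.hub_bait,
            up_line=up_line,
            down_line=down_line,
            normalize=config.normalize,
            pseudo=config.pseudo,
            fc_min=config.fc_min,
            alpha=config.alpha,
            missing_policy=config.missing_policy,
            floor=config.floor,
        )
        quant.to_csv(out / "modulation.tsv", sep="\t")
        counts = quant["concordance"].value_counts().to_dict()
        summary["concordance_counts"] = {
            c: int(counts.get(c, 0)) for c in ("concordant", "discordant", "unchanged")
        }
        log_lines.append(
            "quantify: " + json.dumps(summary["concordance_counts"], sort_keys=True)
        )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ---- score against ground truth -------------------------------------
    if truth is not None:
        stage = "score"
        try:
            expected = truth.expected_categories.reindex(
                assignment.categories.index
            ).fillna("bait_independent_unassigned")
            metrics = recovery_metrics(assignment, expected)
            metrics.to_csv(out / "recovery_metrics.tsv", sep="\t")
            summary["recovery"] = {
                cat: {
                    "precision": None
                    if pd.isna(row["precision"])
                    else round(float(row["precision"]), 6),
                    "recall": None
                    if pd.isna(row["recall"])
                    else round(float(row["recall"]), 6),
                }
                for cat, row in metrics.iterrows()
            }
            coupled_in_scope = truth.coupled & hub_s
            concordant = frozenset(
                quant.index[quant["concordance"] == "concordant"]
            )
            summary["concordant_recovery"] = {
                "n_coupled_in_scope": len(coupled_in_scope),
                "recall": round(
                    len(coupled_in_scope & concordant) / len(coupled_in_scope), 6
                )
                if coupled_in_scope
                else None,
                "precision": round(
                    len(coupled_in_scope & concordant) / len(concordant), 6
                )
                if concordant
                else None,
            }
            log_lines.append(
                "score: " + json.dumps(summary["concordant_recovery"], sort_keys=True)
            )
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, str(e)) from e

    # ---- enrich ----------------------------------------------------------
    if config.deu_table is not None:
        stage = "enrich"
        try:
            deu = read_deu_table(config.deu_table)
            collections = {
                name: read_gene_set(p) for name, p in sorted(config.gene_sets.items())
            }
            res, sig = deu_overlap_analysis(
                deu, collections, alpha=config.enrich_alpha
            )
            res.to_csv(out / "deu_overlap.tsv", sep="\t")
            summary["deu"] = {
                "n_significant_genes": len(sig),
                "overlaps": {
                    name: {"k": int(r["k"]), "p": float(r["p"])}
                    for name, r in res.iterrows()
                },
            }
            log_lines.append(f"enrich: {len(sig)} DEU genes")
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, str(e)) from e

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary
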