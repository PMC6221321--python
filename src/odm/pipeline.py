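"""End-to-end orchestration of the seven analysis stages.

``run_pipeline`` executes DE calling, pattern clustering, functional
enrichment, harm association, regulator enrichment, regulator scoring and
compound reversal on a plain-text input bundle, writing one provenance-
stamped TSV per stage into a run directory.  Re-running with the same
configuration reproduces byte-identical outputs.
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

from . import clustering, enrichment, harm, regulators, reversal, timecourse
from .dataset import read_expression
from .simulate import DEPENDENCE_EFFECTS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "validate_inputs", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    expression: str
    samples: str
    harm_scores: str
    gene_sets: str
    annotation: str
    peaks: str
    compounds: str
    opioids: tuple[str, ...] = ("morphine", "heroin")
    dependence_effects: tuple[str, ...] = DEPENDENCE_EFFECTS
    alpha: float = 0.05
    fc_threshold: float = 1.2
    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 1000
    n_perm: int = 999
    window_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.fc_threshold <= 0:
            raise ValueError("alpha and fc_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        for key in ("expression", "samples", "harm_scores", "gene_sets",
                    "annotation", "peaks", "compounds"):
            if key in raw and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        for key in ("opioids", "dependence_effects"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_bed(path: str | Path, errors: list[str]) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                errors.append(f"{path}:{ln}: BED line has fewer than 3 fields")
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                errors.append(f"{path}:{ln}: non-integer BED coordinates")
                continue
            if start >= end:
                errors.append(f"{path}:{ln}: BED interval start >= end")


def validate_inputs(config: PipelineConfig) -> dict[str, list[str]]:
    """Format and consistency checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings: list[str] = []
    for key in ("expression", "samples", "harm_scores", "gene_sets",
                "annotation", "peaks", "compounds"):
        if not Path(getattr(config, key)).exists():
            errors.append(f"missing input file: {key} = {getattr(config, key)}")
    if errors:
        return {"errors": errors, "warnings": warnings}

    try:
        ds = read_expression(config.expression, config.samples)
    except Exception as err:
        errors.append(f"expression matrix: {err}")
        return {"errors": errors, "warnings": warnings}
    for drug in config.opioids:
        if drug not in ds.drugs:
            errors.append(f"configured opioid {drug!r} absent from the sample sheet")
    for drug in ds.drugs:
        times = ds.times_for(drug)
        if 0.0 not in times:
            errors.append(f"drug {drug!r}: no time-0 control samples")
        counts = ds.samples.loc[ds.samples["drug"] == drug].groupby("time_hours").size()
        if (counts < 2).any():
            warnings.append(f"drug {drug!r}: fewer than 2 replicates at some time point")

    try:
        table = harm.read_harm_scores(config.harm_scores)
        missing = [d for d in ds.drugs if d not in table.columns]
        if missing:
            errors.append(f"harm-score table is missing drugs: {missing}")
    except Exception as err:
        errors.append(f"harm scores: {err}")

    try:
        sets = enrichment.read_gmt(config.gene_sets)
        set_genes = {g for members in sets.values() for g in members}
        expr_genes = {g.upper() for g in ds.gene_ids}
        if set_genes:
            overlap = len(set_genes & expr_genes) / len(set_genes)
            if overlap < 0.8:
                warnings.append(
                    f"gene-set universe overlaps expression genes at only {overlap:.0%}"
                )
    except ValueError as err:
        errors.append(str(err))

    _check_bed(config.peaks, errors)
    try:
        enrichment.read_annotation(config.annotation)
    except Exception as err:
        errors.append(f"annotation: {err}")
    try:
        reversal.read_compound_library(config.compounds)
    except Exception as err:
        errors.append(f"compound library: {err}")
    return {"errors": errors, "warnings": warnings}


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str,
           index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# odm stage={stage} config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


@dataclass
class PipelineResult:
    run_dir: Path
    deg_calls: dict[str, pd.DataFrame] = field(default_factory=dict)
    clusterings: dict[str, clustering.ClusteringResult] = field(default_factory=dict)
    associations: dict[str, pd.DataFrame] = field(default_factory=dict)
    regulator_enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    regulator_scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    reversal_rankings: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run every stage; outputs land in ``out_dir``.

    Stage order: de -> cluster -> enrich(functional) -> associate ->
    enrich(regulator) -> score-regulators -> reverse.  A stage failure
    raises :class:`PipelineError` naming the stage; outputs of completed
    stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(run_dir=out)
    report = validate_inputs(config)
    if report["errors"]:
        raise PipelineError("validate", "bad-input", "; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning("validate: %s", w)

    ds = read_expression(config.expression, config.samples)
    harm_table = harm.read_harm_scores(config.harm_scores)

    # --- stage 1: differential expression ---------------------------------
    try:
        fits = timecourse.fit_dataset(ds)
        for drug in config.opioids:
            calls = timecourse.call_degs(
                ds, drug, alpha=config.alpha, fc_threshold=config.fc_threshold,
                fits=fits[drug],
            )
            result.deg_calls[drug] = calls
            _write(calls, out / f"deg_{drug}.tsv", config, "de")
            logger.info("de[%s]: %d/%d genes called DE", drug,
                        int(calls.is_de.sum()), len(calls))
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("de", "fit-failure", str(err)) from err

    # --- stage 2: pattern clustering --------------------------------------
    try:
        for drug in config.opioids:
            calls = result.deg_calls[drug]
            de_genes = list(calls.index[calls.is_de])
            if len(de_genes) < config.k_min + 1:
                logger.warning("cluster[%s]: only %d DE genes, skipping", drug, len(de_genes))
                continue
            profiles = clustering.profiles_from_fits(fits[drug], de_genes)
            k_hi = min(config.k_max, len(de_genes) - 1)
            res = clustering.select_k_by_asw(
                profiles, range(config.k_min, k_hi + 1),
                n_restarts=config.n_restarts, seed=config.seed,
            )
            clustering.label_clusters(res, calls)
            result.clusterings[drug] = res
            tab = pd.DataFrame({
                "cluster": res.assignments,
                "label": [
                    "{}_{}".format(*reversed(res.labels.get(c, ("?", "?"))))
                    for c in res.assignments
                ],
            })
            _write(tab, out / f"clusters_{drug}.tsv", config, "cluster")
            asw = pd.DataFrame(
                {"K": list(res.asw_by_k), "asw": list(res.asw_by_k.values())}
            )
            _write(asw, out / f"asw_by_k_{drug}.tsv", config, "cluster", index=False)
            logger.info("cluster[%s]: K=%d (ASW=%.3f)", drug, res.K, res.asw)
    except Exception as err:
        raise PipelineError("cluster", "clustering-failure", str(err)) from err

    # --- stage 3: functional enrichment -----------------------------------
    try:
        gmt = enrichment.read_gmt(config.gene_sets)
        functional = enrichment.GeneSetCollection(
            sets={k: set(v) for k, v in gmt.items()},
            universe={g.upper() for g in ds.gene_ids},
        )
        for drug, res in result.clusterings.items():
            frames = []
            for c in sorted(set(res.assignments)):
                members = set(res.assignments.index[res.assignments == c])
                rows = enrichment.enrich(members, functional, mode="functional",
                                         alpha=config.alpha)
                rows = rows.assign(cluster=c)
                frames.append(rows)
            tab = pd.concat(frames)
            _write(tab, out / f"enrichment_functional_{drug}.tsv", config, "enrich")
    except Exception as err:
        raise PipelineError("enrich-functional", "enrichment-failure", str(err)) from err

    # --- stage 4: harm association ----------------------------------------
    try:
        for drug in config.opioids:
            assoc = harm.associate(result.deg_calls[drug], fits, harm_table,
                                   alpha=config.alpha)
            result.associations[drug] = assoc
            _write(assoc, out / f"associations_{drug}.tsv", config, "associate",
                   index=False)
            logger.info("associate[%s]: %d significant pairs", drug,
                        int(assoc.significant.sum()))
    except Exception as err:
        raise PipelineError("associate", "association-failure", str(err)) from err

    # --- stage 5: regulator enrichment ------------------------------------
    try:
        anno = enrichment.read_annotation(config.annotation)
        peaks = enrichment.read_peaks(config.peaks)
        reg_sets = enrichment.build_regulator_sets(peaks, anno, config.window_bp)
        dep_assoc: dict[str, set[str]] = {}
        for drug in config.opioids:
            assoc = result.associations[drug]
            sig = assoc.loc[
                assoc.significant & assoc.effect.isin(config.dependence_effects)
            ]
            dep_assoc[drug] = set(sig["gene"].str.upper())
            rows = enrichment.enrich(dep_assoc[drug], reg_sets, mode="regulator",
                                     alpha=config.alpha)
            result.regulator_enrichment[drug] = rows
            _write(rows, out / f"enrichment_regulator_{drug}.tsv", config, "enrich")
    except Exception as err:
        raise PipelineError("enrich-regulator", "enrichment-failure", str(err)) from err

    # --- stage 6: regulator scoring ---------------------------------------
    try:
        effects = list(harm_table.index)
        for drug in config.opioids:
            rows = []
            enriched = result.regulator_enrichment[drug]
            hits = enriched.index[enriched.significant]
            for reg in hits:
                rset = enrichment.RegulatorSet(regulator=reg,
                                               targets=reg_sets.sets[reg])
                for phase in ("IE", "M", "L"):
                    in_phase = {
                        g for g in dep_assoc[drug]
                        if result.deg_calls[drug].loc[g, "phase"] == phase
                    }
                    score = regulators.dependence_score(rset, in_phase, fits[drug], phase)
                    if score.n_regulated == 0:
                        continue
                    eff_scores = regulators.association_scores(
                        rset, result.associations[drug], fits[drug], phase,
                        effects=effects,
                    )
                    rows.append({
                        "regulator": reg, "phase": phase, "direction": score.direction,
                        "n": score.n_regulated,
                        "dependence_score": score.dependence_score,
                        "signed_score": score.signed_score,
                        **{f"score_{e}": v for e, v in eff_scores.items()},
                    })
            tab = pd.DataFrame(rows)
            if len(tab):
                tab = tab.sort_values(["dependence_score", "regulator"],
                                      ascending=[False, True], kind="mergesort")
            result.regulator_scores[drug] = tab
            _write(tab, out / f"regulators_{drug}.tsv", config, "score-regulators",
                   index=False)
    except Exception as err:
        raise PipelineError("score-regulators", "scoring-failure", str(err)) from err

    # --- stage 7: compound reversal ---------------------------------------
    try:
        library = reversal.read_compound_library(config.compounds)
        for drug in config.opioids:
            calls = result.deg_calls[drug]
            genes = sorted(dep_assoc[drug])
            if not genes:
                logger.warning("reverse[%s]: no dependence-associated DEGs", drug)
                result.reversal_rankings[drug] = pd.DataFrame()
                continue
            weights = {}
            for g in genes:
                fc = float(calls.loc[g, "signed_fc"])
                weights[g] = np.sign(fc) * abs(fc)
            query = reversal.QuerySignature(weights)
            ranked = reversal.rank_compounds(query, library, n_perm=config.n_perm,
                                             seed=config.seed)
            tab = pd.DataFrame([
                {
                    "compound": r.compound, "score": r.score, "n_shared": r.n_shared,
                    "perm_p": r.perm_p, "opposite_genes": ",".join(r.opposite_genes),
                }
                for r in ranked
            ])
            result.reversal_rankings[drug] = tab
            _write(tab, out / f"reversal_{drug}.tsv", config, "reverse", index=False)
    except Exception as err:
        raise PipelineError("reverse", "reversal-failure", str(err)) from err

    return result
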