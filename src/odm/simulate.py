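"""Synthetic multi-drug time-course bundles with planted ground truth.

The generator emulates a striatal drug-exposure study: six drugs of abuse
(two opioids), expression sampled at 0/1/2/4/8 h with three biological
replicates, the time-0 naive control shared across drugs.  On top of flat
noisy baselines it plants

* differentially expressed genes per opioid following smooth rise/plateau/
  return templates peaking in the immediate-early, middle or late phase,
  scaled to a configured linear fold change;
* harm-effect-associated genes whose per-drug response amplitudes are an
  exact affine image of a latent per-effect score vector (the harm-score
  table adds small noise on top of that latent vector);
* near-miss genes whose fold change sits just below the DE threshold;
* transcription-regulator peak sets placed inside/outside the 1000-bp
  TSS/TTS windows of a toy genome annotation;
* a compound library containing one exact-negation reverser of the planted
  dependence signature among random decoys.

The *structure* of the ground truth (which genes are planted, their
patterns, regulator target maps) is a deterministic function of the
configuration; the seed only moves noise and nuisance values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, sample_name, write_expression

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_harm_scores",
    "simulate_regulators_and_compounds",
    "write_bundle",
    "PATTERNS",
    "DEFAULT_DRUGS",
    "DEFAULT_OPIOIDS",
    "DEFAULT_EFFECTS",
    "DEPENDENCE_EFFECTS",
]

DEFAULT_DRUGS = ("morphine", "heroin", "cocaine", "methamphetamine", "ethanol", "nicotine")
DEFAULT_OPIOIDS = ("morphine", "heroin")

#: Twelve expert-rated harm dimensions (three physical-harm, four
#: dependence-related, three social-harm scores, plus intoxication and
#: conditioned place preference).
DEFAULT_EFFECTS = (
    "physical_harm_overall",
    "physical_harm_acute",
    "physical_harm_chronic",
    "dependence",
    "physical_dependence",
    "psychological_dependence",
    "pleasure",
    "social_harm_overall",
    "social_harm_other",
    "health_care_costs",
    "intoxication",
    "cpp",
)

DEPENDENCE_EFFECTS = ("dependence", "physical_dependence", "psychological_dependence")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def template_ie(t: np.ndarray) -> np.ndarray:
    """Immediate-early: rise within the first hour, return towards baseline."""
    t = np.asarray(t, float)
    return _smoothstep(t / 0.8) - 0.9 * _smoothstep((t - 1.4) / 3.6)


def template_m(t: np.ndarray) -> np.ndarray:
    """Middle: peak plateau around 3 h, return towards baseline."""
    t = np.asarray(t, float)
    return _smoothstep((t - 1.0) / 1.2) - 0.9 * _smoothstep((t - 3.4) / 3.6)


def template_l(t: np.ndarray) -> np.ndarray:
    """Late: rise after 3 h, hold through 8 h."""
    t = np.asarray(t, float)
    return _smoothstep((t - 3.0) / 2.5)


#: pattern label -> (direction, phase, unit template); peak |value| is 1.
PATTERNS: dict[str, tuple[str, str, object]] = {
    "IE_up": ("up", "IE", template_ie),
    "M_up": ("up", "M", template_m),
    "L_up": ("up", "L", template_l),
    "IE_down": ("down", "IE", template_ie),
    "M_down": ("down", "M", template_m),
    "L_down": ("down", "L", template_l),
}
_PATTERN_ORDER = list(PATTERNS)


@dataclass
class SimulationConfig:
    """Study-design and planting parameters for the synthetic bundle."""

    n_genes: int = 1000
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    opioids: tuple[str, ...] = DEFAULT_OPIOIDS
    time_grid_hours: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0)
    n_replicates: int = 3
    noise_sd: float = 0.2
    de_fraction: float = 0.1
    fc_planted: float = 2.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    effects: tuple[str, ...] = DEFAULT_EFFECTS
    assoc_effects: tuple[str, ...] = DEPENDENCE_EFFECTS
    assoc_genes_per_effect: int = 3
    harm_noise_sd: float = 0.05
    near_miss_fc: float = 1.1
    n_regulators: int = 20
    n_dependence_regulators: int = 5
    n_compounds: int = 200
    n_gene_sets: int = 30
    genes_per_set: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        tg = np.asarray(self.time_grid_hours, float)
        if tg[0] != 0.0 or np.any(np.diff(tg) <= 0):
            raise ValueError("time_grid_hours: must be strictly increasing and start at 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates: need at least 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd: must be positive")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction: must be in [0, 1)")
        if self.fc_planted < 1.0:
            raise ValueError("fc_planted: linear fold change must be >= 1")
        if not 1.0 <= self.near_miss_fc:
            raise ValueError("near_miss_fc: must be >= 1")
        if not set(self.opioids) <= set(self.drugs):
            raise ValueError("opioids: must be a subset of drugs")
        if not set(self.assoc_effects) <= set(self.effects):
            raise ValueError("assoc_effects: must be a subset of effects")
        if self.n_genes < 1:
            raise ValueError("n_genes: must be positive")

    @property
    def n_de(self) -> int:
        return int(round(self.n_genes * self.de_fraction))

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:06d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What was planted; downstream stages are scored against this."""

    de_genes: dict[str, dict[str, dict]] = field(default_factory=dict)
    near_miss_genes: dict[str, list[str]] = field(default_factory=dict)
    effect_associated_genes: dict[str, list[str]] = field(default_factory=dict)
    #: gene -> drug -> log2 response amplitude at the template peak
    amplitudes: dict[str, dict[str, float]] = field(default_factory=dict)
    #: effect -> latent per-drug score vector (harm table = this + noise)
    latent_scores: dict[str, list[float]] = field(default_factory=dict)
    regulator_targets: dict[str, list[str]] = field(default_factory=dict)
    reversal_compounds: list[str] = field(default_factory=list)

    def structural_summary(self) -> dict:
        """Seed-invariant part of the truth (identity and layout only)."""
        return {
            "de_genes": {d: {g: v["pattern"] for g, v in gs.items()} for d, gs in self.de_genes.items()},
            "near_miss_genes": self.near_miss_genes,
            "effect_associated_genes": self.effect_associated_genes,
            "regulator_targets": self.regulator_targets,
            "reversal_compounds": self.reversal_compounds,
        }


def _plant_layout(config: SimulationConfig) -> tuple[dict, list[int], dict]:
    """Deterministic plant layout: which gene index gets which pattern where.

    Opioid A takes indices ``[0, n_de)``; opioid B shares the
    effect-associated genes and fills with fresh indices; near-miss genes
    follow.  Returns (per-opioid {index: pattern}, near-miss indices,
    {effect: [indices]}).
    """
    n_de = config.n_de
    assoc_total = len(config.assoc_effects) * config.assoc_genes_per_effect if n_de else 0
    if assoc_total > n_de:
        raise ValueError(
            "assoc_genes_per_effect: dependence-associated plants "
            f"({assoc_total}) exceed planted DE genes per opioid ({n_de})"
        )
    assoc_idx: dict[str, list[int]] = {}
    k = 0
    for eff in config.assoc_effects:
        if n_de == 0:
            assoc_idx[eff] = []
            continue
        assoc_idx[eff] = list(range(k, k + config.assoc_genes_per_effect))
        k += config.assoc_genes_per_effect
    per_opioid: dict[str, dict[int, str]] = {}
    for o, opioid in enumerate(config.opioids):
        if o == 0:
            idx = list(range(0, n_de))
        else:
            fresh_lo = n_de + (o - 1) * (n_de - assoc_total)
            idx = list(range(assoc_total)) + list(range(fresh_lo, fresh_lo + n_de - assoc_total))
        per_opioid[opioid] = {g: _PATTERN_ORDER[j % 6] for j, g in enumerate(idx)}
    n_near = n_de // 5
    lo = n_de + (len(config.opioids) - 1) * (n_de - assoc_total)
    near_idx = list(range(lo, min(lo + n_near, config.n_genes)))
    return per_opioid, near_idx, assoc_idx


def simulate_expression(config: SimulationConfig, seed: int | None = None) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate the expression matrix and its ground truth.

    The time-0 control replicates are generated once and shared across all
    drugs (the naive-control convention).  Identical seeds give bit-identical
    output; the planted layout does not depend on the seed at all.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tg = np.asarray(config.time_grid_hours, float)
    reps = config.n_replicates
    n = config.n_genes
    genes = config.gene_ids
    per_opioid, near_idx, assoc_idx = _plant_layout(config)

    truth = GroundTruth()
    log2fc = np.log2(config.fc_planted)

    # latent per-effect score vectors and affine amplitudes for planted
    # associated genes: amplitude_d = a0 + b * s_d with the opioid minimum
    # pinned at log2(fc_planted) so the gene stays DE in both opioids.
    drug_list = list(config.drugs)
    opioid_pos = [drug_list.index(o) for o in config.opioids]
    amp_by_gene: dict[int, np.ndarray] = {}
    for eff in config.assoc_effects:
        s = rng.uniform(0.0, 3.0, size=len(drug_list))
        truth.latent_scores[eff] = [float(v) for v in s]
        b = 0.35 / max(np.std(s), 0.3)
        for gi in assoc_idx[eff]:
            a0 = log2fc - b * min(s[p] for p in opioid_pos)
            amp_by_gene[gi] = a0 + b * s
        truth.effect_associated_genes[eff] = [genes[i] for i in assoc_idx[eff]]

    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(n)
    ctrl = baseline[:, None] + config.noise_sd * rng.standard_normal((n, reps))

    cols: list[str] = []
    meta: dict[str, list] = {"drug": [], "time_hours": [], "replicate": []}
    blocks: list[np.ndarray] = []
    for drug in drug_list:
        signal = np.zeros((n, tg.size))
        planted = per_opioid.get(drug, {})
        for gi, pattern in planted.items():
            direction, phase, tpl = PATTERNS[pattern]
            amp = amp_by_gene.get(gi, np.full(len(drug_list), log2fc))[drug_list.index(drug)]
            sgn = 1.0 if direction == "up" else -1.0
            signal[gi] += sgn * amp * tpl(tg)
            rec = truth.de_genes.setdefault(drug, {})
            rec[genes[gi]] = {
                "pattern": pattern,
                "phase": phase,
                "direction": direction,
                "signed_fc": float(sgn * 2.0 ** amp),
            }
            truth.amplitudes.setdefault(genes[gi], {})[drug] = float(sgn * amp)
        if drug in config.opioids:
            for j, gi in enumerate(near_idx):
                direction, phase, tpl = PATTERNS[_PATTERN_ORDER[j % 6]]
                sgn = 1.0 if direction == "up" else -1.0
                signal[gi] += sgn * np.log2(config.near_miss_fc) * tpl(tg)
            truth.near_miss_genes[drug] = [genes[i] for i in near_idx]
        # associated genes respond in every drug, not only the opioids
        if drug not in config.opioids:
            for gi, amps in amp_by_gene.items():
                a = amps[drug_list.index(drug)]
                pattern = per_opioid[config.opioids[0]][gi]
                direction, phase, tpl = PATTERNS[pattern]
                sgn = 1.0 if direction == "up" else -1.0
                signal[gi] += sgn * a * tpl(tg)
                truth.amplitudes.setdefault(genes[gi], {})[drug] = float(sgn * a)
        block = np.repeat(baseline[:, None], tg.size * reps, axis=1)
        block += config.noise_sd * rng.standard_normal((n, tg.size * reps))
        block[:, :reps] = ctrl  # shared naive control at t=0
        block[:, reps:] += np.repeat(signal[:, 1:], reps, axis=1)
        blocks.append(block)
        for t in tg:
            for r in range(1, reps + 1):
                cols.append(sample_name(drug, t, r))
                meta["drug"].append(drug)
                meta["time_hours"].append(float(t))
                meta["replicate"].append(r)

    values = pd.DataFrame(np.hstack(blocks), index=pd.Index(genes, name="gene"), columns=cols)
    samples = pd.DataFrame(meta, index=pd.Index(cols, name="sample"))
    return ExpressionDataset(values, samples), truth


def simulate_harm_scores(
    drugs: list[str],
    effects: list[str],
    planted: dict[str, list[str]],
    truth: GroundTruth,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Harm-score table (effects x drugs) in the style of published expert
    drug-harm ratings (scores roughly on a 0-3 scale).

    Effects listed in ``planted`` reuse the latent score vector that the
    associated genes' amplitudes were drawn from (plus ``noise_sd`` jitter),
    so the association stage can recover the planted pairs; all other
    effects get scores independent of the expression data.
    """
    if not effects:
        raise ValueError("effect list is empty")
    if len(drugs) < 4:
        raise ValueError("need at least 4 drugs for meaningful correlation tests")
    rng = np.random.default_rng(seed)
    rows = []
    for eff in effects:
        if eff in planted and eff in truth.latent_scores:
            s = np.asarray(truth.latent_scores[eff], float)[: len(drugs)]
            s = s + noise_sd * rng.standard_normal(len(drugs))
        else:
            s = rng.uniform(0.0, 3.0, size=len(drugs))
        rows.append(s)
    return pd.DataFrame(rows, index=pd.Index(effects, name="effect"), columns=list(drugs))


# ---------------------------------------------------------------------------
# toy genome, regulator peaks, compound library
# ---------------------------------------------------------------------------

_GENE_SPACING = 10_000
_GENE_LENGTH = 2_000
_PEAK_WIDTH = 200


def _toy_annotation(config: SimulationConfig) -> pd.DataFrame:
    """One transcript per gene on chr1; alternating strands."""
    genes = config.gene_ids
    start = _GENE_SPACING * (1 + np.arange(len(genes)))
    strand = np.where(np.arange(len(genes)) % 2 == 0, "+", "-")
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": start,
            "end": start + _GENE_LENGTH,
            "gene": genes,
            "strand": strand,
        }
    )


def _regulator_layout(config: SimulationConfig, truth: GroundTruth) -> dict[str, list[str]]:
    """Deterministic regulator -> target map.

    The first ``n_dependence_regulators`` regulators target overlapping
    slices of the dependence-associated genes (plus deterministic filler);
    the rest target arbitrary slices of the remaining genes.
    """
    genes = config.gene_ids
    assoc = sorted({g for gs in truth.effect_associated_genes.values() for g in gs})
    targets: dict[str, list[str]] = {}
    others = [g for g in genes if g not in set(assoc)]
    for k in range(config.n_regulators):
        name = f"REG{k:03d}"
        if k < config.n_dependence_regulators and assoc:
            take = assoc[k % max(len(assoc), 1):] + assoc[: k % max(len(assoc), 1)]
            picked = take[: max(2, int(np.ceil(0.7 * len(assoc))))]
            filler = others[(7 * k) % len(others):(7 * k) % len(others) + 3]
            targets[name] = sorted(set(picked) | set(filler))
        else:
            lo = (13 * k) % max(len(others) - 12, 1)
            targets[name] = sorted(others[lo:lo + 12])
    return targets


def simulate_regulators_and_compounds(
    truth: GroundTruth, config: SimulationConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Toy annotation, regulator peaks, and a compound-signature library.

    Returns ``(annotation, peaks, compounds)``:

    * ``annotation``: chrom/start/end/gene/strand, 0-based half-open.
    * ``peaks``: chrom/start/end/regulator rows; each target gene of a
      regulator gets one peak inside the 1000-bp upstream window of its
      strand-oriented TSS, plus decoy peaks in gene deserts.
    * ``compounds``: compound/gene/signed_fc/p rows; ``CMPD_REV`` is the
      exact negation of the planted dependence signature, every other
      compound is a random decoy.
    """
    rng = np.random.default_rng(seed)
    anno = _toy_annotation(config)
    truth.regulator_targets = _regulator_layout(config, truth)
    pos = {g: i for i, g in enumerate(anno["gene"])}
    rows = []
    for reg, targets in truth.regulator_targets.items():
        for g in targets:
            i = pos[g]
            start, end, strand = int(anno["start"][i]), int(anno["end"][i]), anno["strand"][i]
            offset = int(rng.integers(150, 800))  # upstream distance of peak midpoint
            if strand == "+":
                mid = start - offset
            else:
                mid = end + offset
            rows.append(("chr1", mid - _PEAK_WIDTH // 2, mid + _PEAK_WIDTH // 2, reg))
        # decoy peak in a gene desert, > 1 kb away from any gene window
        desert = int(anno["end"].iloc[-1]) + _GENE_SPACING + 5000
        rows.append(("chr1", desert, desert + _PEAK_WIDTH, reg))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "regulator"])
    peaks = peaks.sort_values(["start", "regulator"], kind="mergesort").reset_index(drop=True)

    # planted dependence signature: associated genes with signed linear FC
    signature: dict[str, float] = {}
    for eff in truth.effect_associated_genes:
        for g in truth.effect_associated_genes[eff]:
            amp = truth.amplitudes[g][config.opioids[0]]
            signature[g] = float(np.sign(amp) * 2.0 ** abs(amp))
    genes = config.gene_ids
    crows = []
    rev_id = "CMPD_REV"
    for g in sorted(signature):
        crows.append((rev_id, g, -signature[g], 0.001))
    sig_genes = sorted(signature)
    for k in range(1, config.n_compounds):
        cid = f"CMPD{k:04d}"
        # decoys share a few signature genes so every compound is comparable
        n_entries = int(rng.integers(20, 40))
        chosen = list(rng.choice(genes, size=n_entries, replace=False))
        chosen += list(rng.choice(sig_genes, size=min(3, len(sig_genes)), replace=False))
        for g in sorted(set(chosen)):
            fc = float(rng.uniform(1.3, 4.0) * rng.choice([-1.0, 1.0]))
            p = float(rng.uniform(0.0, 0.049))
            crows.append((cid, g, fc, p))
        # a couple of entries that the load-time DEG filter must drop
        weak = rng.choice(genes, size=2, replace=False)
        crows.append((cid, str(weak[0]), float(rng.uniform(-1.15, 1.15)), 0.01))
        crows.append((cid, str(weak[1]), 2.0, float(rng.uniform(0.06, 0.9))))
    compounds = pd.DataFrame(crows, columns=["compound", "gene", "signed_fc", "p"])
    truth.reversal_compounds = [rev_id]
    return anno, peaks, compounds


def _gene_sets(config: SimulationConfig, truth: GroundTruth) -> dict[str, list[str]]:
    """Functional gene sets: the first six mirror the planted patterns of the
    first opioid (enrichable), the rest are deterministic slices."""
    genes = config.gene_ids
    sets: dict[str, list[str]] = {}
    opioid = config.opioids[0]
    by_pattern: dict[str, list[str]] = {}
    for g, rec in truth.de_genes.get(opioid, {}).items():
        by_pattern.setdefault(rec["pattern"], []).append(g)
    for pat, members in sorted(by_pattern.items()):
        if len(members) >= 2:
            sets[f"SET_{pat}"] = sorted(members)
    for k in range(len(sets), config.n_gene_sets):
        lo = (k * 37) % max(config.n_genes - config.genes_per_set, 1)
        sets[f"SET_RAND{k:03d}"] = genes[lo:lo + config.genes_per_set]
    return sets


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------


def write_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate everything and write the full plain-text input bundle.

    Files: ``expression.tsv``, ``samples.csv``, ``harm_scores.csv``,
    ``gene_sets.gmt``, ``annotation.gff3``, ``peaks.bed``,
    ``compounds.tsv``, ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = simulate_expression(config)
    harm = simulate_harm_scores(
        list(config.drugs),
        list(config.effects),
        {e: truth.effect_associated_genes.get(e, []) for e in config.assoc_effects},
        truth,
        seed=config.seed + 1,
        noise_sd=config.harm_noise_sd,
    )
    anno, peaks, compounds = simulate_regulators_and_compounds(truth, config, seed=config.seed + 2)
    sets = _gene_sets(config, truth)

    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.csv",
        "harm_scores": out / "harm_scores.csv",
        "gene_sets": out / "gene_sets.gmt",
        "annotation": out / "annotation.gff3",
        "peaks": out / "peaks.bed",
        "compounds": out / "compounds.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression(ds, paths["expression"], paths["samples"])
    harm.to_csv(paths["harm_scores"])
    with open(paths["gene_sets"], "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in anno.iterrows():
            # GFF3 is 1-based closed
            fh.write(
                f"chr1\todm\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.gene};Name={r.gene}\n"
            )
    peaks.to_csv(paths["peaks"], sep="\t", header=False, index=False)
    compounds.to_csv(paths["compounds"], sep="\t", index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(config).items()},
                "structure": truth.structural_summary(),
                "amplitudes": truth.amplitudes,
                "latent_scores": truth.latent_scores,
            },
            fh,
            indent=1,
        )
    return paths
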