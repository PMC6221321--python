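"""Dependence and per-effect association scores for enriched regulators.

A regulator active in phase P is scored by the dependence-associated DE
genes it regulates within P: the dependence score is the sum over those
genes of each gene's maximum absolute fold change inside the phase window
(relative to the control time point); association scores repeat the sum per
harm effect over the genes associated with that effect.  Scores are stored
as magnitudes with a separate majority direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timecourse import PHASE_WINDOWS

__all__ = ["RegulatorScore", "max_abs_fc_in_phase", "dependence_score", "association_scores"]


def max_abs_fc_in_phase(fit, phase: str) -> float:
    """2^max over the phase window of |fitted(t) - fitted(0)|; >= 1 always.

    ``fit`` is a TimeCourseFit (or any object with ``grid_times``/``grid``
    and a ``log2_ratio`` over it).
    """
    if phase not in PHASE_WINDOWS:
        raise ValueError(f"unknown phase {phase!r}")
    lo, hi = PHASE_WINDOWS[phase]
    grid = np.asarray(getattr(fit, "grid_times", None) if hasattr(fit, "grid_times") else fit.grid)
    ratio = np.asarray(fit.log2_ratio, float)
    mask = (grid > lo) & (grid <= hi)
    if not mask.any():
        raise ValueError(f"no evaluation points inside phase {phase}")
    return float(2.0 ** np.max(np.abs(ratio[mask])))


@dataclass
class RegulatorScore:
    regulator: str
    phase: str
    n_regulated: int
    dependence_score: float
    direction: str | None
    genes: list[str] = field(default_factory=list)
    effect_scores: dict[str, float] = field(default_factory=dict)

    @property
    def signed_score(self) -> float:
        """Sign-folded presentation (negative for down-regulating sets)."""
        return -self.dependence_score if self.direction == "down" else self.dependence_score


def _phase_fc(fits, gene: str, phase: str) -> tuple[float, str]:
    i = fits.index_of(gene)
    lo, hi = PHASE_WINDOWS[phase]
    mask = (fits.grid > lo) & (fits.grid <= hi)
    ratio = fits.log2_ratio[i, mask]
    j = int(np.argmax(np.abs(ratio)))
    return float(2.0 ** abs(ratio[j])), ("up" if ratio[j] >= 0 else "down")


def dependence_score(
    regulator_set,
    dep_assoc_degs: set[str] | list[str],
    fits,
    phase: str,
) -> RegulatorScore:
    """Sum of max-|FC|-in-phase over the regulator's dependence-associated
    DEGs; N and the majority direction come along for the report."""
    if phase not in PHASE_WINDOWS:
        raise ValueError(f"unknown phase {phase!r}")
    genes = sorted(set(regulator_set.targets) & {g.upper() for g in dep_assoc_degs})
    total = 0.0
    ups = 0
    for g in genes:
        fc, direction = _phase_fc(fits, g, phase)
        total += fc
        ups += direction == "up"
    if genes:
        direction = "up" if ups * 2 >= len(genes) else "down"
    else:
        direction = None
    return RegulatorScore(
        regulator=regulator_set.regulator,
        phase=phase,
        n_regulated=len(genes),
        dependence_score=total if genes else 0.0,
        direction=direction,
        genes=genes,
    )


def association_scores(
    regulator_set,
    association_results,
    fits,
    phase: str,
    effects: list[str] | None = None,
) -> dict[str, float]:
    """Per-effect association score: the dependence-score sum restricted to
    the regulated genes significantly associated with each effect."""
    sig = association_results.loc[association_results["significant"]]
    if effects is None:
        effects = list(dict.fromkeys(association_results["effect"]))
    out: dict[str, float] = {}
    for eff in effects:
        genes = set(sig.loc[sig["effect"] == eff, "gene"].str.upper())
        genes &= set(regulator_set.targets)
        out[eff] = float(sum(_phase_fc(fits, g, phase)[0] for g in sorted(genes)))
    return out
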