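"""Cohort-level spectral quality gating.

Whole spectra (never single metabolite estimates) are excluded on two
criteria:

- CRLB rule: per metabolite, the cutoff is ``crlb_multiplier`` times the
  cohort median of its absolute CRLB (mM); a subject is excluded when
  strictly more than half of the analysed metabolites exceed their
  cutoffs.  Using absolute (mM) bounds avoids the bias that
  percentage-CRLB rules introduce when concentrations differ between
  groups.
- Linewidth rule: the fitted common Gauss linewidth, a shim-quality
  measure, must not exceed the region's maximum.

Cohort medians are computed over all subjects (both groups pooled) in a
single pass, before any exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_ANALYZED = ("NAA", "NAAG", "Cr", "PCr", "GPC", "PCho", "mI")


@dataclass(frozen=True)
class QCPolicy:
    """Region-specific gating thresholds.

    Brain: CRLB cutoff at 1.5x the cohort median, Gauss linewidth <= 7.5 Hz.
    Cord: 2.0x and 10 Hz (the cord tolerates more because its spectral
    quality is intrinsically lower).
    """

    region: str
    crlb_multiplier: float
    gauss_lw_max: float  # Hz
    majority_fraction: float = 0.5
    analyzed_metabolites: tuple[str, ...] = DEFAULT_ANALYZED

    def __post_init__(self) -> None:
        if self.crlb_multiplier <= 1:
            raise ValueError("crlb_multiplier must exceed 1")
        if not 0 < self.majority_fraction < 1:
            raise ValueError("majority_fraction must be in (0, 1)")
        if self.gauss_lw_max <= 0:
            raise ValueError("gauss_lw_max must be positive")

    @classmethod
    def brain(cls, **overrides) -> "QCPolicy":
        kw = dict(region="brain", crlb_multiplier=1.5, gauss_lw_max=7.5)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def cord(cls, **overrides) -> "QCPolicy":
        kw = dict(region="cord", crlb_multiplier=2.0, gauss_lw_max=10.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def for_region(cls, region: str, **overrides) -> "QCPolicy":
        return cls.brain(**overrides) if region == "brain" else cls.cord(**overrides)


def gate_spectra(
    crlb_table: pd.DataFrame,
    linewidths: pd.Series,
    policy: QCPolicy,
) -> tuple[list, list, dict, dict]:
    """Apply the CRLB-median and Gauss-linewidth exclusion rules.

    Parameters
    ----------
    crlb_table:
        Absolute CRLBs in mM; rows = subjects, columns = metabolites.
        Must be complete for ``policy.analyzed_metabolites``.
    linewidths:
        Common Gauss linewidth (Hz) per subject.
    policy:
        Region thresholds.

    Returns
    -------
    (kept subject ids, excluded subject ids, reasons per excluded subject,
    per-metabolite CRLB cutoffs).
    """
    metabolites = list(policy.analyzed_metabolites)
    missing_cols = [m for m in metabolites if m not in crlb_table.columns]
    if missing_cols:
        raise ValueError(f"CRLB table lacks columns for: {missing_cols}")
    sub = crlb_table[metabolites]
    if sub.isna().any().any():
        bad = [
            f"{idx}:{col}"
            for idx, row in sub.iterrows()
            for col in metabolites
            if pd.isna(row[col])
        ]
        raise ValueError(f"missing CRLB entries: {bad}")
    if len(sub) < 3:
        raise ValueError("cohort size must be >= 3 for median-based gating")
    missing_lw = [s for s in sub.index if s not in linewidths.index]
    if missing_lw:
        raise ValueError(f"missing linewidths for subjects: {missing_lw}")

    # single-pass pooled medians over the full cohort, sorted for
    # row-order-independent determinism
    cutoffs = {
        m: policy.crlb_multiplier * float(sub[m].sort_values().median()) for m in metabolites
    }
    threshold = policy.majority_fraction * len(metabolites)

    kept, excluded, reasons = [], [], {}
    for subject in sub.index:
        why = []
        n_over = sum(1 for m in metabolites if sub.at[subject, m] > cutoffs[m])
        if n_over > threshold:  # strictly more than half; ties kept
            why.append(f"crlb:{n_over}/{len(metabolites)} metabolites above cutoff")
        if float(linewidths[subject]) > policy.gauss_lw_max:
            why.append(f"gauss_linewidth:{float(linewidths[subject]):.2f}Hz")
        if why:
            excluded.append(subject)
            reasons[subject] = why
        else:
            kept.append(subject)
    return kept, excluded, reasons, cutoffs
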