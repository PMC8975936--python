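"""Dual-stimulus plate analysis for all-optical high-throughput screening.

Each well is read out twice: once with the light stimulus (receptor-
independent channel) and once with the pharmacological agonist.  After
control anchoring, compounds are classified by which channel(s) they
inhibit: a *double hit* blocks both (acting on the target channel itself),
an *agonist-only* hit blocks only the agonist response (typically a
receptor-level false positive), a *light-only* hit blocks only the light
response.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, UsageError, ValidationError
from .respmodels import DoseResponse, HillFit, hill_fit, pic50

__all__ = [
    "PlateRecord",
    "HitCall",
    "ROLES",
    "CATEGORIES",
    "normalize_plate",
    "classify_hits",
    "concentration_response",
    "round_percent",
]

ROLES = ("test", "dmso", "pos_receptor_block", "pos_channel_block")
CATEGORIES = ("double", "agonist_only", "light_only", "inactive")


@dataclass
class PlateRecord:
    """One well after normalization: % inhibition per stimulation channel."""

    well_id: str
    compound_id: str
    concentration_m: float
    role: str
    resp_light: float
    resp_agonist: float

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}")
        if not (np.isfinite(self.resp_light) and np.isfinite(self.resp_agonist)):
            raise ValidationError("responses must be finite")


@dataclass
class HitCall:
    """Categorical classification of one test compound."""

    compound_id: str
    category: str
    inhibition_light: float
    inhibition_agonist: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"category must be one of {CATEGORIES}")


def round_percent(value: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding, as printed in screening summaries."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_plate(raw: pd.DataFrame) -> list[PlateRecord]:
    """Anchor raw per-well responses to plate controls, per channel.

    ``raw`` is a long-format frame with columns ``plate, well, compound_id,
    role, concentration_M, resp_light, resp_agonist`` holding raw (e.g.
    ΔF/F0) responses.  Per plate and channel, the DMSO-control mean maps to
    0% inhibition and the full-block (``pos_channel_block``) control mean to
    100%; the mapping is linear in between.  Requires >= 3 DMSO wells and
    >= 1 full-block well per plate.
    """
    required = {"plate", "well", "compound_id", "role", "concentration_M",
                "resp_light", "resp_agonist"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    records: list[PlateRecord] = []
    for plate, grp in raw.groupby("plate"):
        dmso = grp[grp["role"] == "dmso"]
        block = grp[grp["role"] == "pos_channel_block"]
        if len(dmso) < 3 or len(block) < 1:
            raise ValidationError(
                f"plate {plate!r} needs >= 3 DMSO and >= 1 full-block control wells"
            )
        anchors = {}
        for ch in ("resp_light", "resp_agonist"):
            d0, b0 = dmso[ch].mean(), block[ch].mean()
            if d0 == b0:
                raise ValidationError(f"plate {plate!r}: degenerate controls in {ch}")
            anchors[ch] = (d0, b0)
        for _, row in grp.iterrows():
            inh = {
                ch: 100.0 * (anchors[ch][0] - row[ch]) / (anchors[ch][0] - anchors[ch][1])
                for ch in ("resp_light", "resp_agonist")
            }
            records.append(
                PlateRecord(
                    well_id=str(row["well"]),
                    compound_id=str(row["compound_id"]),
                    concentration_m=float(row["concentration_M"]),
                    role=str(row["role"]),
                    resp_light=inh["resp_light"],
                    resp_agonist=inh["resp_agonist"],
                )
            )
    return records


def classify_hits(
    records: list[PlateRecord], threshold: float = 50.0
) -> tuple[list[HitCall], dict]:
    """Quadrant hit classification of normalized test wells.

    A channel counts as inhibited when its % inhibition is >= ``threshold``.
    Returns per-compound calls and a summary with counts and percentages of
    the total tested (half-up rounded to 2 decimals).
    """
    if not (0.0 < threshold < 100.0):
        raise UsageError("threshold must lie in (0, 100) % inhibition")
    tests = [r for r in records if r.role == "test"]
    if not tests:
        raise DegenerateInputError("no test wells to classify")
    calls: list[HitCall] = []
    for r in tests:
        light_hit = r.resp_light >= threshold
        ago_hit = r.resp_agonist >= threshold
        if light_hit and ago_hit:
            cat = "double"
        elif ago_hit:
            cat = "agonist_only"
        elif light_hit:
            cat = "light_only"
        else:
            cat = "inactive"
        calls.append(
            HitCall(
                compound_id=r.compound_id,
                category=cat,
                inhibition_light=r.resp_light,
                inhibition_agonist=r.resp_agonist,
            )
        )
    n = len(calls)
    counts = {c: sum(1 for h in calls if h.category == c) for c in CATEGORIES}
    summary = {
        "n_tested": n,
        "threshold": threshold,
        "counts": counts,
        "percentages": {c: round_percent(100.0 * k / n) for c, k in counts.items()},
    }
    return calls, summary


def concentration_response(
    records: list[PlateRecord], min_concentrations: int = 6, min_replicates: int = 2
) -> tuple[HillFit, float]:
    """IC50 fit and pIC50 for one compound across concentrations.

    ``records`` are normalized wells (``resp_*`` as % inhibition) of a single
    compound; the light-channel inhibition is fitted with a log-axis 4PL.
    """
    if not records:
        raise DegenerateInputError("no records supplied")
    ids = {r.compound_id for r in records}
    if len(ids) != 1:
        raise UsageError("records must belong to a single compound")
    conc = np.array([r.concentration_m for r in records])
    resp = np.array([r.resp_light for r in records])
    uniq, counts = np.unique(conc, return_counts=True)
    if uniq.size < min_concentrations:
        raise ValidationError(f"need >= {min_concentrations} distinct concentrations")
    if counts.min() < min_replicates:
        raise ValidationError(f"need >= {min_replicates} replicates per concentration")
    data = DoseResponse(dose=conc, response=resp, units="mol/L", log_axis=True)
    fit = hill_fit(data)
    return fit, pic50(fit)
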