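"""Isotope zonation and sulfate–methane transition zone (SMTZ) detection.

Microbial methane oxidation enriches residual methane in ¹³C, so horizons
whose δ¹³C-CH₄ is markedly less negative than the biogenic source signature
record past or ongoing oxidation. Horizons are classified against two
thresholds on the VPDB scale:

* ``oxidized``      — δ¹³C-CH₄ strictly above the oxidation threshold (default −37‰)
* ``source``        — δ¹³C-CH₄ strictly below the source threshold (default −52‰)
* ``intermediate``  — between the thresholds
* ``unconstrained`` — δ¹³C-CH₄ not measured

The oxidized/source contrast feeds the open-system isotope mass balance in
:mod:`permaom.fractionation`. Two shift extractors are provided:

* :func:`max_isotope_shift` — the largest δ contrast between an oxidized
  horizon and a source horizon lying below it (the "highest change"
  statistic). Being an extreme-value statistic it is biased high under
  per-horizon measurement noise.
* :func:`mean_isotope_shift` — the zone-mean contrast, unbiased under
  additive iid noise; preferred for parameter-recovery checks.

The SMTZ detector locates the depth interval where downward-diffusing
sulfate and upward-diffusing methane cross after each profile is normalized
to its own maximum, requiring genuinely opposing gradients across the
interval.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from statistics import fmean
from typing import Optional

from .errors import InsufficientDataError, ParameterError, ValidationError
from .profiles import CoreProfile

__all__ = [
    "ZoneLabel",
    "ZonationLabel",
    "IsotopeShift",
    "SmtzInterval",
    "classify_horizons",
    "max_isotope_shift",
    "mean_isotope_shift",
    "detect_smtz",
    "DEFAULT_OX_THRESHOLD",
    "DEFAULT_SOURCE_THRESHOLD",
]

#: δ¹³C-CH₄ above which a horizon counts as oxidized (‰ VPDB).
DEFAULT_OX_THRESHOLD = -37.0
#: δ¹³C-CH₄ below which a horizon counts as a methane source (‰ VPDB).
DEFAULT_SOURCE_THRESHOLD = -52.0


class ZoneLabel(str, enum.Enum):
    OXIDIZED = "oxidized"
    SOURCE = "source"
    INTERMEDIATE = "intermediate"
    UNCONSTRAINED = "unconstrained"


@dataclass(frozen=True)
class ZonationLabel:
    """Classification of one horizon."""

    depth_mbsf: float
    label: ZoneLabel


@dataclass(frozen=True)
class IsotopeShift:
    """An oxidized/source δ¹³C-CH₄ pair and its contrast.

    ``delta_o`` is the signature of the oxidized layer at ``depth_o``;
    ``delta_p`` the produced/trapped (source) signature at ``depth_p``,
    which must lie below the oxidized layer (methane moves upward into the
    oxidation zone).
    """

    delta_o: float
    delta_p: float
    depth_o: float
    depth_p: float

    def __post_init__(self) -> None:
        if not self.depth_p > self.depth_o:
            raise ValidationError(
                f"source depth ({self.depth_p} mbsf) must lie below the "
                f"oxidized depth ({self.depth_o} mbsf)"
            )

    @property
    def shift(self) -> float:
        """δ_o − δ_p in ‰."""
        return self.delta_o - self.delta_p


@dataclass(frozen=True)
class SmtzInterval:
    """Depth interval bracketing the sulfate–methane crossing."""

    top_mbsf: float
    bottom_mbsf: float
    sulfate_at_top: float
    methane_at_bottom: float

    def __post_init__(self) -> None:
        if not self.top_mbsf < self.bottom_mbsf:
            raise ValidationError("SMTZ interval top must lie above its bottom")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top_mbsf + self.bottom_mbsf)

    def __contains__(self, depth: float) -> bool:
        return self.top_mbsf <= depth <= self.bottom_mbsf


def _check_thresholds(ox_threshold: float, source_threshold: float) -> None:
    if not ox_threshold > source_threshold:
        raise ParameterError(
            f"ox_threshold ({ox_threshold}) must exceed source_threshold "
            f"({source_threshold})"
        )


def classify_horizons(
    profile: CoreProfile,
    ox_threshold: float = DEFAULT_OX_THRESHOLD,
    source_threshold: float = DEFAULT_SOURCE_THRESHOLD,
) -> list[ZonationLabel]:
    """Label every horizon by its δ¹³C-CH₄ against the two thresholds.

    Returns exactly one label per record, in depth order. Classification is
    a deterministic function of δ¹³C-CH₄ and the thresholds.
    """
    _check_thresholds(ox_threshold, source_threshold)
    labels = []
    for rec in profile:
        if rec.d13c_ch4 is None:
            lab = ZoneLabel.UNCONSTRAINED
        elif rec.d13c_ch4 > ox_threshold:
            lab = ZoneLabel.OXIDIZED
        elif rec.d13c_ch4 < source_threshold:
            lab = ZoneLabel.SOURCE
        else:
            lab = ZoneLabel.INTERMEDIATE
        labels.append(ZonationLabel(rec.depth_mbsf, lab))
    return labels


def max_isotope_shift(
    profile: CoreProfile,
    ox_threshold: float = DEFAULT_OX_THRESHOLD,
    source_threshold: float = DEFAULT_SOURCE_THRESHOLD,
) -> Optional[IsotopeShift]:
    """Largest δ¹³C contrast between an oxidized horizon and a deeper source.

    Over all pairs (i oxidized, j source) with ``depth_j > depth_i``, returns
    the pair maximizing ``δ_i − δ_j``; ``None`` when no qualifying pair
    exists. Ties are broken toward the smallest depth separation, then the
    shallowest oxidized horizon (the most local, least transport-confounded
    signal).
    """
    labels = classify_horizons(profile, ox_threshold, source_threshold)
    recs = profile.records
    oxidized = [
        (r.depth_mbsf, r.d13c_ch4)
        for r, l in zip(recs, labels)
        if l.label is ZoneLabel.OXIDIZED
    ]
    source = [
        (r.depth_mbsf, r.d13c_ch4)
        for r, l in zip(recs, labels)
        if l.label is ZoneLabel.SOURCE
    ]
    best: Optional[IsotopeShift] = None
    best_key: Optional[tuple[float, float, float]] = None
    for d_o, v_o in oxidized:
        for d_p, v_p in source:
            if not d_p > d_o:
                continue
            # lexicographic: maximize shift, minimize separation, minimize depth_o
            key = (-(v_o - v_p), d_p - d_o, d_o)
            if best_key is None or key < best_key:
                best_key = key
                best = IsotopeShift(delta_o=v_o, delta_p=v_p, depth_o=d_o, depth_p=d_p)
    return best


def mean_isotope_shift(
    profile: CoreProfile,
    ox_threshold: float = DEFAULT_OX_THRESHOLD,
    source_threshold: float = DEFAULT_SOURCE_THRESHOLD,
) -> Optional[IsotopeShift]:
    """Zone-mean δ¹³C contrast between the oxidized and source zones.

    ``delta_o``/``delta_p`` are the means over all oxidized / all source
    horizons, carried at the mean depth of each zone. Under additive iid
    measurement noise this contrast is an unbiased estimate of the expected
    oxidized-minus-source signature difference, unlike the extreme-pair
    statistic of :func:`max_isotope_shift`. Returns ``None`` when either
    zone is empty or the mean source depth does not lie below the mean
    oxidized depth.
    """
    labels = classify_horizons(profile, ox_threshold, source_threshold)
    recs = profile.records
    ox = [(r.depth_mbsf, r.d13c_ch4) for r, l in zip(recs, labels) if l.label is ZoneLabel.OXIDIZED]
    src = [(r.depth_mbsf, r.d13c_ch4) for r, l in zip(recs, labels) if l.label is ZoneLabel.SOURCE]
    if not ox or not src:
        return None
    depth_o = fmean(d for d, _ in ox)
    depth_p = fmean(d for d, _ in src)
    if not depth_p > depth_o:
        return None
    return IsotopeShift(
        delta_o=fmean(v for _, v in ox),
        delta_p=fmean(v for _, v in src),
        depth_o=depth_o,
        depth_p=depth_p,
    )


def detect_smtz(
    profile: CoreProfile,
    sulfate_floor: float = 1.0,
) -> Optional[SmtzInterval]:
    """Locate the SMTZ as the crossing of max-normalized sulfate and methane.

    Both analytes are linearly interpolated between measured depths and
    scaled to their own profile maximum; the detector returns the pair of
    adjacent measured depths bracketing the first (shallowest) sign change
    of (sulfate_norm − methane_norm) across which sulfate decreases,
    methane increases, and sulfate at the interval top is at least
    ``sulfate_floor`` (mM). Returns ``None`` when no such crossing exists
    (e.g. sulfate absent, or gradients not opposing).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 records carry both sulfate and methane.
    """
    pts = [
        (r.depth_mbsf, r.sulfate, r.ch4)
        for r in profile
        if r.sulfate is not None and r.ch4 is not None
    ]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"SMTZ detection needs >=3 records with both sulfate and methane; "
            f"got {len(pts)}"
        )
    depths = [d for d, _, _ in pts]
    so4 = [s for _, s, _ in pts]
    ch4 = [m for _, _, m in pts]
    s_max, m_max = max(so4), max(ch4)
    if s_max <= 0.0 or m_max <= 0.0:
        return None
    diff = [s / s_max - m / m_max for s, m in zip(so4, ch4)]
    for i in range(len(pts) - 1):
        a, b = diff[i], diff[i + 1]
        crossing = (a > 0.0 >= b) or (a == 0.0 and b < 0.0)
        if not crossing:
            continue
        if not (so4[i] > so4[i + 1] and ch4[i] < ch4[i + 1]):
            continue  # gradients not opposing across this segment
        if so4[i] < sulfate_floor:
            continue
        return SmtzInterval(
            top_mbsf=depths[i],
            bottom_mbsf=depths[i + 1],
            sulfate_at_top=so4[i],
            methane_at_bottom=ch4[i + 1],
        )
    return None
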