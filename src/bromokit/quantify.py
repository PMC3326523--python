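"""Spot quantification, QC filtering, and Kac-dependent interaction calling.

Quantification integrates a circular region of interest at each expected
spot center and subtracts a local background estimated as the median of a
surrounding annulus (times the ROI area).  Corrected intensities are
floored at zero.

Calling logic: a probe is *positive* when its corrected intensity clears
the membrane's positive threshold.  An interaction is Kac-*dependent* when
the probe is positive and its sequence-identical unmodified control is
not; probe-and-control-positive pairs are retained but flagged
Kac-independent (the "gray" class).  Positive intensities are binned into
weak/medium/strong categories (tertiles by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import ArrayLayout, Spot
from .synth import MembraneImage

QC_FLAGS = ("his_ab_reactive", "no_kac_ab_signal", "proline_adjacent")
CATEGORIES = ("none", "weak", "medium", "strong")


@dataclass
class SpotIntensityTable:
    """Per-spot raw/background/corrected intensities for one membrane."""

    membrane_id: str
    probe_id: str  # identity of the reader domain probed (or control stain)
    frame: pd.DataFrame  # columns: label, role, row, col, raw, background,
    # corrected, exposure_time
    exposure_time: float = 5.0

    def corrected(self, label: str, role: str = "probe") -> float:
        sel = self.frame[(self.frame.label == label) & (self.frame.role == role)]
        if sel.empty:
            raise KeyError(f"no {role} row for {label!r}")
        return float(sel.corrected.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# membrane_id={self.membrane_id} probe={self.probe_id} "
                f"exposure_time={self.exposure_time}\n"
            )
            self.frame.to_csv(fh, sep="\t", index=False)


def _roi_masks(
    image: MembraneImage, spot: Spot, roi_pad: float = 3.0, annulus_width: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    geom = image.geometry
    cy, cx = geom.center(spot.row, spot.col)
    h, w = image.pixels.shape
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"spot ({spot.row},{spot.col}) center outside image")
    r_roi = geom.radius + roi_pad
    r_out = r_roi + annulus_width
    y0, y1 = int(max(0, cy - r_out - 1)), int(min(h, cy + r_out + 2))
    x0, x1 = int(max(0, cx - r_out - 1)), int(min(w, cx + r_out + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    patch = image.pixels[y0:y1, x0:x1]
    return patch[dist <= r_roi], patch[(dist > r_roi) & (dist <= r_out)]


def quantify_spots(
    image: MembraneImage,
    layout: ArrayLayout,
    probe_id: str = "",
    roi_pad: float = 3.0,
    annulus_width: float = 4.0,
) -> SpotIntensityTable:
    """Integrate each layout spot on the image; registration is taken as
    exact (synthetic membranes share the layout geometry)."""
    rows = []
    for spot in layout.spots:
        roi, annulus = _roi_masks(image, spot, roi_pad, annulus_width)
        raw = float(np.sum(roi))
        background = float(np.median(annulus)) if annulus.size else 0.0
        signed = raw - background * roi.size
        corrected = max(signed, 0.0)
        rows.append(
            {
                "label": spot.peptide.label,
                "role": spot.role,
                "control_partner": spot.control_partner or "",
                "row": spot.row,
                "col": spot.col,
                "raw": raw,
                "background": background,
                "corrected": corrected,
                "corrected_signed": signed,
                "exposure_time": image.exposure_time,
            }
        )
    return SpotIntensityTable(
        membrane_id=layout.membrane_id,
        probe_id=probe_id,
        frame=pd.DataFrame(rows),
        exposure_time=image.exposure_time,
    )


def select_exposure(tables: Sequence[SpotIntensityTable], clip_raw: float = 5.5e6
                    ) -> SpotIntensityTable:
    """From an exposure series, keep per spot the latest exposure whose raw
    integral is below the clipping ceiling."""
    if not tables:
        raise ValueError("empty exposure series")
    ordered = sorted(tables, key=lambda t: t.exposure_time)
    base = ordered[0].frame.copy()
    for t in ordered[1:]:
        newer = t.frame
        ok = newer.raw < clip_raw
        base.loc[ok.values, ["raw", "background", "corrected", "exposure_time"]] = (
            newer.loc[ok.values, ["raw", "background", "corrected", "exposure_time"]].values
        )
    return replace(ordered[0], frame=base, exposure_time=float("nan"))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _kac_positions(layout: ArrayLayout, label: str) -> list[int]:
    for s in layout.spots:
        if s.peptide.label == label:
            return sorted(m.position for m in s.peptide.mods if m.kind == "ac")
    return []


def proline_adjacent_labels(layout: ArrayLayout, window: int = 2) -> set[str]:
    """Peptides with a proline within ±``window`` residues of an acetyl-
    lysine; these commonly escape anti-Kac antibody recognition."""
    out: set[str] = set()
    for s in layout.spots:
        histone = s.peptide.histone()
        for m in s.peptide.mods:
            if m.kind != "ac":
                continue
            lo = max(s.peptide.start, m.position - window)
            hi = min(s.peptide.end, m.position + window)
            neighborhood = histone.residues[lo - 1 : hi]
            if "P" in neighborhood:
                out.add(s.peptide.label)
    return out


def qc_filter(
    table: SpotIntensityTable,
    layout: ArrayLayout,
    his_ab_table: SpotIntensityTable | None = None,
    kac_ab_table: SpotIntensityTable | None = None,
    his_ab_threshold: float | None = None,
    kac_ab_threshold: float | None = None,
) -> SpotIntensityTable:
    """Annotate the table with QC flags from the control stains.

    * spots reactive on the His-antibody-only membrane are excluded
      (``his_ab_reactive``);
    * acetylated spots with no anti-Kac signal are flagged
      ``no_kac_ab_signal`` (failed on-membrane acetyl incorporation or
      antibody failure) and excluded from interaction statistics;
    * peptides with proline adjacent to a Kac are annotated
      ``proline_adjacent`` (informational).

    Thresholds default to the robust positive threshold of the respective
    control table.  Filtering is idempotent: re-applying with the same
    controls reproduces the same flags.
    """
    frame = table.frame.copy()
    if list(frame.label) != [s.peptide.label for s in layout.spots]:
        raise ValueError("intensity table does not match layout")
    flags: list[set[str]] = [set() for _ in range(len(frame))]

    if his_ab_table is not None:
        if len(his_ab_table.frame) != len(frame):
            raise ValueError("His-antibody table does not share the layout")
        thr = (
            his_ab_threshold
            if his_ab_threshold is not None
            else positive_threshold(his_ab_table)
        )
        for i, value in enumerate(his_ab_table.frame.corrected):
            if value >= thr:
                flags[i].add("his_ab_reactive")

    ac_labels = {
        s.peptide.label
        for s in layout.spots
        if any(m.kind == "ac" for m in s.peptide.mods)
    }
    if kac_ab_table is not None:
        if len(kac_ab_table.frame) != len(frame):
            raise ValueError("anti-Kac table does not share the layout")
        thr = (
            kac_ab_threshold
            if kac_ab_threshold is not None
            else positive_threshold(kac_ab_table)
        )
        for i, (label, value) in enumerate(
            zip(kac_ab_table.frame.label, kac_ab_table.frame.corrected)
        ):
            if label in ac_labels and value < thr:
                flags[i].add("no_kac_ab_signal")

    pro = proline_adjacent_labels(layout)
    for i, label in enumerate(frame.label):
        if label in pro:
            flags[i].add("proline_adjacent")

    frame["qc_flags"] = [";".join(sorted(f)) for f in flags]
    frame["excluded"] = [
        bool(f & {"his_ab_reactive", "no_kac_ab_signal"}) for f in flags
    ]
    return replace(table, frame=frame)


# ---------------------------------------------------------------------------
# interaction calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionCall:
    label: str
    probe_id: str
    category: str
    kac_dependent: bool
    qc_flags: frozenset[str] = frozenset()
    corrected: float = 0.0
    control_corrected: float = float("nan")

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "none" and self.kac_dependent:
            raise ValueError("category none implies not Kac-dependent")


@dataclass(frozen=True)
class CallThresholds:
    """Thresholding configuration for interaction calling.

    ``positive`` overrides the per-membrane robust default (median +
    3·1.4826·MAD of control-spot corrected intensities).  ``bins`` fixes
    the weak/medium/strong boundaries; by default they are the tertiles of
    the positive probe intensities of the membrane.
    """

    positive: float | None = None
    bins: tuple[float, float] | None = None


def positive_threshold(table: SpotIntensityTable) -> float:
    """Robust positive threshold from control-spot corrected intensities
    (median + 3 × 1.4826 × MAD); falls back to all spots when the membrane
    carries no controls."""
    frame = table.frame
    column = "corrected_signed" if "corrected_signed" in frame.columns else "corrected"
    controls = frame[frame.role == "unmod_control"][column].to_numpy()
    if controls.size == 0:
        controls = frame[column].to_numpy()
    med = float(np.median(controls))
    mad = float(np.median(np.abs(controls - med)))
    return med + 3.0 * 1.4826 * mad


def _category_bins(
    positives: np.ndarray, thresholds: CallThresholds
) -> tuple[float, float]:
    if thresholds.bins is not None:
        lo, hi = thresholds.bins
        if not lo <= hi:
            raise ValueError("bin edges must be ordered")
        return lo, hi
    if positives.size == 0:
        return math.inf, math.inf
    t1, t2 = np.quantile(positives, [1 / 3, 2 / 3])
    return float(t1), float(t2)


def call_interactions(
    table: SpotIntensityTable,
    thresholds: CallThresholds | None = None,
) -> list[InteractionCall]:
    """Call per-probe interactions with Kac-dependence verdicts.

    Requires the table to be QC-annotated (``qc_filter``) or raw (no
    ``qc_flags`` column = no exclusions).  Raises on probes whose control
    row is missing.  Monotone: raising a probe's corrected intensity never
    demotes its category; raising its control's never promotes
    Kac-dependence.
    """
    thresholds = thresholds or CallThresholds()
    frame = table.frame
    has_flags = "qc_flags" in frame.columns
    positive = (
        thresholds.positive
        if thresholds.positive is not None
        else positive_threshold(table)
    )
    controls = {
        r.label: float(r.corrected)
        for r in frame[frame.role == "unmod_control"].itertuples()
    }
    probe_rows = frame[frame.role == "probe"]
    pos_values = probe_rows.corrected.to_numpy()
    bins = _category_bins(pos_values[pos_values >= positive], thresholds)

    calls: list[InteractionCall] = []
    for r in probe_rows.itertuples():
        flags = (
            frozenset(f for f in r.qc_flags.split(";") if f) if has_flags else frozenset()
        )
        if "his_ab_reactive" in flags:
            continue  # excluded outright: never yields a call
        control_label = getattr(r, "control_partner", None)
        control_value = None
        if control_label:
            control_value = controls.get(control_label)
        else:
            # fall back to the layout convention: control shares the window
            base = r.label  # probes are labelled window+marks
            window = base.split(")")[0] + ")"
            control_value = controls.get(window)
        if control_value is None:
            raise KeyError(f"missing control row for probe {r.label!r}")
        excluded = "no_kac_ab_signal" in flags
        value = float(r.corrected)
        probe_pos = value >= positive and not excluded
        control_pos = control_value >= positive
        if not probe_pos:
            category = "none"
        elif value >= bins[1]:
            category = "strong"
        elif value >= bins[0]:
            category = "medium"
        else:
            category = "weak"
        kac_dependent = probe_pos and not control_pos
        calls.append(
            InteractionCall(
                label=r.label,
                probe_id=table.probe_id,
                category=category,
                kac_dependent=kac_dependent,
                qc_flags=flags,
                corrected=value,
                control_corrected=control_value,
            )
        )
    return calls


def calls_to_frame(calls: Iterable[InteractionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": c.label,
                "probe_id": c.probe_id,
                "category": c.category,
                "kac_dependent": c.kac_dependent,
                "qc_flags": ";".join(sorted(c.qc_flags)),
                "corrected": c.corrected,
                "control_corrected": c.control_corrected,
            }
            for c in calls
        ]
    )


def crosstalk_effect(
    table: SpotIntensityTable,
    context_label: str,
    central_only_label: str,
) -> float:
    """Enhancement ratio of a flanking-mark context over the central-Kac-
    only peptide; +inf signals de-novo enablement (context binds while the
    central mark alone does not)."""
    context = table.corrected(context_label)
    central = table.corrected(central_only_label)
    if central == 0.0:
        return math.inf if context > 0 else math.nan
    return context / central


def relative_peak_intensity(areas: Mapping[str, float]) -> dict[str, float]:
    """Relative abundance as each peak area over the summed area of all
    peaks; fractions sum to 1."""
    if any(v < 0 for v in areas.values()):
        raise ValueError("peak areas must be nonnegative")
    total = float(sum(areas.values()))
    if total <= 0:
        raise ValueError("at least one positive peak area required")
    return {label: value / total for label, value in areas.items()}
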