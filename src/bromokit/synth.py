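"""Seeded ground-truth generators: affinity landscapes, membrane images,
ITC traces, and motif-planted reader-domain sequences.

Every generator here is a pure function of its parameters and a single
integer seed, so any planted truth can be reconstructed exactly for
verification.  The membranes emulate chemiluminescent SPOT blots probed at
1 μM reader concentration: the mean spot signal is ``gain · θ`` with
equilibrium occupancy ``θ = c / (c + K_D)`` of the immobilized peptide
(reader in vast excess, no depletion), and the default gain places a
K_D = 500 μM spot — the practical detection limit of the format — at a
per-pixel signal-to-noise ratio of 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .arrays import ArrayLayout, Spot
from .histones import AMINO_ACIDS
from .itc import (
    BindingParameters,
    TitrationExperiment,
    c_value,
    simulate_isotherm,
)

#: sentinel dissociation constant for spots that do not bind at all
NO_BINDING = float("inf")


def _spawn(seed: int, *keys: int) -> np.random.Generator:
    """Independent, reproducible substream for (seed, keys)."""
    return np.random.default_rng([seed, *keys])


def _label_key(label: str) -> int:
    """Stable 32-bit key for a peptide label (layout-order independent)."""
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


# ---------------------------------------------------------------------------
# affinity landscapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeRules:
    """Generative rules for planted dissociation constants.

    The defaults mirror the phenomenology of acetyl-lysine reader arrays:
    mono-Kac binders fall log-uniformly in the low-micromolar to
    sub-millimolar window, each additional compatible acetyl-lysine
    multiplies affinity by ``kac_gain`` (avidity / bidentate recognition),
    flanking phosphorylation enhances and flanking trimethylation
    suppresses binding, and a small fraction of spots binds independently
    of acetylation (their unmodified controls bind too).
    """

    binder_fraction: float = 0.3
    mono_kd_range: tuple[float, float] = (3e-6, 300e-6)
    kac_gain: float = 20.0
    ph_factor: float = 5.0
    me3_factor: float = 0.2
    kac_independent_fraction: float = 0.0
    nonbinder_kd: float = 5e-3  # K_D handed to "non-binder" epitopes

    def __post_init__(self) -> None:
        for name in ("binder_fraction", "kac_independent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.kac_gain <= 0 or self.ph_factor <= 0 or self.me3_factor <= 0:
            raise ValueError("rule factors must be positive")


@dataclass
class AffinityLandscape:
    """Planted K_D per peptide label plus the rules that fired."""

    kd: dict[str, float]
    provenance: dict[str, list[str]] = field(default_factory=dict)
    rules: LandscapeRules = field(default_factory=LandscapeRules)
    seed: int = 0

    def __getitem__(self, label: str) -> float:
        return self.kd[label]

    def is_binder(self, label: str, threshold: float = 500e-6) -> bool:
        return self.kd[label] <= threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.kd),
                "kd_molar": [self.kd[k] for k in self.kd],
                "rules": [";".join(self.provenance.get(k, [])) for k in self.kd],
            }
        )


def _epitope_key(spot: Spot) -> str:
    """Epitope identity: parent + anchor (first) acetyl-lysine position.

    All context variants of one central Kac share a baseline draw, so
    context effects compose multiplicatively on a common reference.
    """
    ac = sorted(m.position for m in spot.peptide.mods if m.kind == "ac")
    anchor = ac[0] if ac else 0
    return f"{spot.peptide.parent}:{anchor}"


def synth_affinity_landscape(
    layout: ArrayLayout,
    rules: LandscapeRules | None = None,
    seed: int = 0,
) -> AffinityLandscape:
    """Assign a ground-truth K_D to every spot of a layout.

    Rule composition is multiplicative and commutative:
    ``K_D = base / kac_gain^(n_ac - 1) · ph_factor^-n_ph · (1/me3_factor)^-n_me3``
    for binder epitopes; unmodified controls of Kac-dependent binders get
    the ``NO_BINDING`` sentinel; Kac-independent binders hand their base
    K_D to probe and control alike.
    """
    rules = rules or LandscapeRules()
    kd: dict[str, float] = {}
    prov: dict[str, list[str]] = {}

    # per-epitope draws keyed independently of layout order
    epitope_cache: dict[str, tuple[bool, bool, float]] = {}

    def epitope_draw(key: str) -> tuple[bool, bool, float]:
        if key not in epitope_cache:
            rng = _spawn(seed, _label_key(key))
            binder = rng.random() < rules.binder_fraction
            kac_independent = rng.random() < rules.kac_independent_fraction
            lo, hi = rules.mono_kd_range
            base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            epitope_cache[key] = (binder, kac_independent, base)
        return epitope_cache[key]

    control_keys: dict[str, str] = {}
    for spot in layout.spots:
        label = spot.peptide.label
        if spot.role != "probe":
            continue
        key = _epitope_key(spot)
        if spot.control_partner:
            control_keys[spot.control_partner] = key
        binder, kac_independent, base = epitope_draw(key)
        fired = []
        if not binder:
            kd[label] = rules.nonbinder_kd
            prov[label] = ["nonbinder"]
            continue
        value = base
        fired.append(f"mono_base={base:.3e}")
        n_ac = spot.peptide.count("ac")
        if n_ac > 1:
            value /= rules.kac_gain ** (n_ac - 1)
            fired.append(f"kac_gain^{n_ac - 1}")
        n_ph = spot.peptide.count("ph")
        if n_ph:
            value /= rules.ph_factor**n_ph
            fired.append(f"ph_factor^{n_ph}")
        n_me3 = spot.peptide.count("me3")
        if n_me3:
            value /= rules.me3_factor**n_me3
            fired.append(f"me3_penalty^{n_me3}")
        if kac_independent:
            fired.append("kac_independent")
        kd[label] = value
        prov[label] = fired

    for spot in layout.spots:
        label = spot.peptide.label
        if spot.role == "probe":
            continue
        if spot.role == "mutant_control":
            # anchor-Asn -> Ala null: no acetyl-lysine recognition at all
            kd[label] = kd.get(label, NO_BINDING)
            continue
        key = control_keys.get(label)
        if key is None:
            kd[label] = NO_BINDING
            prov[label] = ["orphan_control"]
            continue
        binder, kac_independent, base = epitope_draw(key)
        if binder and kac_independent:
            kd[label] = base
            prov[label] = ["kac_independent_control"]
        else:
            kd[label] = NO_BINDING
            prov[label] = ["control"]
    return AffinityLandscape(kd, prov, rules, seed)


# ---------------------------------------------------------------------------
# membrane rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembraneGeometry:
    pitch: int = 22  # px between spot centers
    radius: float = 5.0  # spot disk radius, px
    margin: int = 16  # px from image edge to first spot center
    edge_sigma: float = 0.8  # Gaussian edge blur, px

    def center(self, row: int, col: int) -> tuple[float, float]:
        return (self.margin + row * self.pitch, self.margin + col * self.pitch)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise on the signal plus Gaussian read noise."""

    read_sd: float = 25.0
    poisson: bool = True
    background: float = 1000.0


@dataclass
class MembraneImage:
    pixels: np.ndarray  # float; exact means in noise-free mode
    geometry: MembraneGeometry
    exposure_time: float  # minutes
    seed: int
    gain: float
    background: float
    layout_id: str = ""

    def to_uint16(self) -> np.ndarray:
        return np.clip(np.round(self.pixels), 0, 65535).astype(np.uint16)

    def write_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.to_uint16())
        meta = {
            "exposure_time_min": self.exposure_time,
            "seed": self.seed,
            "gain": self.gain,
            "background": self.background,
            "pitch": self.geometry.pitch,
            "radius": self.geometry.radius,
            "margin": self.geometry.margin,
            "layout_id": self.layout_id,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def occupancy(kd: float, probe_conc: float) -> float:
    """Equilibrium occupancy of immobilized peptide by the probe."""
    if math.isinf(kd):
        return 0.0
    return probe_conc / (probe_conc + kd)


def default_gain(
    noise: NoiseModel,
    probe_conc: float = 1e-6,
    detection_limit_kd: float = 500e-6,
    detection_snr: float = 2.0,
) -> float:
    """Gain placing the detection-limit K_D at per-pixel SNR ``detection_snr``."""
    theta = occupancy(detection_limit_kd, probe_conc)
    return detection_snr * noise.read_sd / theta


def render_membrane(
    layout: ArrayLayout,
    landscape: AffinityLandscape,
    probe_conc: float = 1e-6,
    gain: float | None = None,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    exposure_time: float = 5.0,
    reference_exposure: float = 5.0,
    geometry: MembraneGeometry | None = None,
    noise_free: bool = False,
    kd_override: Mapping[str, float] | None = None,
    probe_is_anchor_mutant: bool = False,
) -> MembraneImage:
    """Render a 16-bit-range membrane image for a layout + landscape.

    Spot mean signal above background is ``gain·θ`` scaled linearly by
    ``exposure_time / reference_exposure``; disks get a Gaussian edge blur;
    noise is Poisson on the total expected signal plus Gaussian read noise.
    ``kd_override`` substitutes planted K_D values per label (e.g. zeroed
    anti-Kac reactivity).  ``probe_is_anchor_mutant`` simulates probing with
    an anchor-Asn→Ala protein: all acetyl-lysine-dependent binding is
    abolished while Kac-independent interactions persist.
    """
    if probe_conc <= 0:
        raise ValueError("probe concentration must be positive")
    geometry = geometry or MembraneGeometry()
    noise_model = noise_model or NoiseModel()
    if gain is None:
        gain = default_gain(noise_model, probe_conc)
    rows = max((s.row for s in layout.spots), default=0) + 1
    cols = max((s.col for s in layout.spots), default=0) + 1
    shape = (
        2 * geometry.margin + (rows - 1) * geometry.pitch + 1,
        2 * geometry.margin + (cols - 1) * geometry.pitch + 1,
    )
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    scale = exposure_time / reference_exposure
    for spot in layout.spots:
        label = spot.peptide.label
        if kd_override is not None and label in kd_override:
            kd = kd_override[label]
        else:
            try:
                kd = landscape[label]
            except KeyError:
                raise KeyError(f"landscape missing layout label {label!r}") from None
        if probe_is_anchor_mutant:
            fired = landscape.provenance.get(label, [])
            if not any(f.startswith("kac_independent") for f in fired):
                kd = NO_BINDING
        theta = occupancy(kd, probe_conc)
        if theta == 0.0:
            continue
        cy, cx = geometry.center(spot.row, spot.col)
        dist = np.hypot(yy - cy, xx - cx)
        img += gain * theta * scale * (dist <= geometry.radius)
    if geometry.edge_sigma > 0:
        img = gaussian_filter(img, geometry.edge_sigma)
    img += noise_model.background
    if not noise_free:
        rng = _spawn(seed, 7)
        signal = np.clip(img, 0, None)
        img = rng.poisson(signal).astype(float)
        img += rng.normal(0.0, noise_model.read_sd, size=img.shape)
    img = np.clip(img, 0.0, 65535.0)
    return MembraneImage(
        pixels=img,
        geometry=geometry,
        exposure_time=exposure_time,
        seed=seed,
        gain=gain * scale,
        background=noise_model.background,
        layout_id=layout.membrane_id,
    )


# ---------------------------------------------------------------------------
# ITC traces
# ---------------------------------------------------------------------------


def synth_itc_trace(
    params: BindingParameters,
    experiment: TitrationExperiment,
    injectant_sites: int = 1,
    noise_sd: float = 0.5,
    dilution_heat: float | Sequence[float] = 0.0,
    seed: int = 0,
) -> TitrationExperiment:
    """Fill an experiment skeleton with simulated heats (μcal).

    ``injectant_sites`` models a peptide carrying several equivalent,
    independent reader-binding acetyl-lysines (``params.dh`` is then per
    site).  Constant (or per-injection) dilution heat is added, then
    Gaussian noise; generating truth is recorded in the provenance.
    """
    heats = simulate_isotherm(params, experiment, injectant_sites)
    d = np.asarray(dilution_heat, dtype=float)
    if d.ndim == 0:
        d = np.full(experiment.n_injections, float(d))
    heats = heats + d
    if noise_sd > 0:
        rng = _spawn(seed, 11)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    c = c_value(params, experiment)
    warning = None
    if not 1e-2 <= c <= 1e4:
        warning = f"c-value {c:.3g} outside [0.01, 1e4]"
    return TitrationExperiment(
        cell_conc=experiment.cell_conc,
        syringe_conc=experiment.syringe_conc,
        cell_volume=experiment.cell_volume,
        injection_volumes=list(experiment.injection_volumes),
        temperature=experiment.temperature,
        heats=list(heats),
        dilution_heats=list(d),
        cell_species=experiment.cell_species,
        provenance={
            "true_N": params.n_sites,
            "true_Ka": params.k_a,
            "true_dH": params.dh,
            "injectant_sites": injectant_sites,
            "noise_sd": noise_sd,
            "seed": seed,
            "c_value": c,
            **({"warning": warning} if warning else {}),
        },
    )


def write_itc_csv(experiment: TitrationExperiment, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "injection_index": np.arange(1, experiment.n_injections + 1),
            "volume_ul": np.asarray(experiment.injection_volumes) * 1e6,
            "heat_ucal": experiment.heats,
        }
    )
    if experiment.dilution_heats is not None:
        d = np.asarray(experiment.dilution_heats, dtype=float)
        if d.ndim == 0:
            d = np.full(experiment.n_injections, float(d))
        frame["blank_heat_ucal"] = d
    with open(path, "w") as fh:
        fh.write(
            f"# cell_conc_M={experiment.cell_conc!r} "
            f"syringe_conc_M={experiment.syringe_conc!r} "
            f"cell_volume_L={experiment.cell_volume!r} "
            f"temperature_K={experiment.temperature!r}\n"
        )
        frame.to_csv(fh, index=False)


def read_itc_csv(path: str | Path) -> TitrationExperiment:
    meta: dict[str, float] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                key, _, value = token.partition("=")
                meta[key] = float(value)
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    return TitrationExperiment(
        cell_conc=meta.get("cell_conc_M", 1e-4),
        syringe_conc=meta.get("syringe_conc_M", 1e-3),
        cell_volume=meta.get("cell_volume_L", 1.4e-3),
        injection_volumes=(frame["volume_ul"] * 1e-6).tolist(),
        temperature=meta.get("temperature_K", 288.15),
        heats=frame["heat_ucal"].tolist(),
        dilution_heats=(
            frame["blank_heat_ucal"].tolist()
            if "blank_heat_ucal" in frame
            else None
        ),
    )


# ---------------------------------------------------------------------------
# reader-domain-like sequences with planted signature motifs
# ---------------------------------------------------------------------------

ROMAN_FAMILIES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

_HYDROPHOBIC = "ACFILMVWY"
_TEMPLATE_LEN = 110

# template scaffold offsets (0-based): helix-Z motif near the N terminus,
# P-phi-D before the A helix, the long B-helix signature, anchor position
_ALPHAZ_AT = 6
_PPHID_AT = 40
_ALPHAB_AT = 70


#: acetyl-lysine anchor residue planted right after the B-helix motif;
#: most families carry the canonical Asn, with Asp/Thr stand-ins mirroring
#: the known natural replacements at this position
FAMILY_ANCHORS = {"VI": "D", "VII": "T"}


def _motif_blocks(rng: np.random.Generator, anchor: str = "N") -> list[tuple[int, str]]:
    """Concrete signature-motif instances for one family template."""
    phi = lambda: _HYDROPHOBIC[rng.integers(len(_HYDROPHOBIC))]
    any_aa = lambda: "ACDEFGHIKLMNQRSTVWY"[rng.integers(19)]  # no P in helices
    alpha_z = phi() + any_aa() + any_aa() + phi() + any_aa() + any_aa() + any_aa() + phi()
    p_phi_d = "P" + phi() + "D"
    alpha_b = (
        phi() + any_aa() + any_aa() + "D" + phi() + any_aa() + any_aa()
        + phi() + phi() + any_aa() + "N" + phi() + any_aa() + any_aa()
        + ("Y" if rng.random() < 0.5 else "F")
        + anchor
    )
    return [(_ALPHAZ_AT, alpha_z), (_PPHID_AT, p_phi_d), (_ALPHAB_AT, alpha_b)]


def family_templates(seed: int = 20120330) -> dict[str, str]:
    """Synthetic per-family template sequences embedding the shared
    signature-motif grammar, with family-specific inter-motif regions.

    These are constructed stand-ins for curated reference domains (the
    package ships no database-derived sequences); they reproduce the motif
    architecture, not any real family's residues.
    """
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    templates: dict[str, str] = {}
    for i, family in enumerate(ROMAN_FAMILIES):
        rng = _spawn(seed, 13, i)
        seq = [alphabet[j] for j in rng.integers(len(alphabet), size=_TEMPLATE_LEN)]
        for offset, motif in _motif_blocks(rng, FAMILY_ANCHORS.get(family, "N")):
            seq[offset : offset + len(motif)] = list(motif)
        templates[family] = "".join(seq)
    return templates


def protected_positions(template: str) -> set[int]:
    """0-based positions covered by the planted signature motifs."""
    spans = [
        (_ALPHAZ_AT, _ALPHAZ_AT + 8),
        (_PPHID_AT, _PPHID_AT + 3),
        (_ALPHAB_AT, _ALPHAB_AT + 16),  # B-helix signature + anchor residue
    ]
    out: set[int] = set()
    for a, b in spans:
        out.update(range(a, min(b, len(template))))
    return out


def synth_brd_sequences(
    templates: Mapping[str, str] | None = None,
    n_per_family: int = 6,
    mutation_rate: float = 0.15,
    protect_motifs: bool = True,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Point-mutated copies of family templates: (id, family, sequence).

    ``protect_motifs`` exempts the planted signature-motif positions from
    mutation so the motif scanner keeps finding them at any rate.
    """
    if not 0.0 <= mutation_rate < 0.5:
        raise ValueError("mutation_rate must be in [0, 0.5)")
    templates = templates or family_templates()
    alphabet = sorted(AMINO_ACIDS)
    out: list[tuple[str, str, str]] = []
    for fi, (family, template) in enumerate(sorted(templates.items())):
        protected = protected_positions(template) if protect_motifs else set()
        for j in range(n_per_family):
            rng = _spawn(seed, 17, fi, j)
            seq = list(template)
            for pos in range(len(seq)):
                if pos in protected:
                    continue
                if rng.random() < mutation_rate:
                    choices = [a for a in alphabet if a != seq[pos]]
                    seq[pos] = choices[rng.integers(len(choices))]
            out.append((f"{family}_{j}", family, "".join(seq)))
    return out
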