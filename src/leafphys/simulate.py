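"""Synthetic-data generators with known ground truth.

Three generators mirror the three assays the package analyses:

* :func:`simulate_recording` — whole-cell currents of a Boltzmann-gated K+
  conductance under a pulse+ramp voltage-clamp protocol;
* :func:`simulate_expression_matrix` — a two-cell-type, replicated log2
  expression matrix with a spiked differentially-expressed fraction;
* :func:`simulate_ratio_images` — dual-excitation fluorescence image pairs
  of protoplast membrane rings whose excitation ratio maps linearly to an
  assigned membrane potential.

Every generator is deterministic for a given seed and returns its ground
truth alongside the data, closing the testing loop for the analysis
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boltzmann import gate_open_probability
from .constants import DEFAULT_TEMPERATURE_K, sphere_surface_area_cm2
from .recording import CurrentRecording, ProtocolSpec

__all__ = [
    "ChannelModelParams",
    "BSC_CHANNEL_PARAMS",
    "MC_CHANNEL_PARAMS",
    "simulate_recording",
    "ExpressionSimSpec",
    "simulate_expression_matrix",
    "RatioImageSpec",
    "RatioImagePair",
    "simulate_ratio_images",
]


# ---------------------------------------------------------------------------
# voltage-clamp recordings
# ---------------------------------------------------------------------------

@dataclass
class ChannelModelParams:
    """Ground-truth biophysics of one simulated protoplast.

    Conductances in mS cm^-2, voltages in mV (true membrane potentials,
    i.e. already on the LJP-corrected scale), time constant in ms, noise in
    pA, diameter in um.
    """

    basal_specific_conductance: float = 0.8
    max_specific_conductance: float = 1.75
    half_activation_voltage: float = 14.5
    gating_charge: float = 1.46
    reversal_potential: float = -31.0
    activation_time_constant: float = 100.0
    current_noise_sd: float = 5.0
    protoplast_diameter: float = 27.4

    def __post_init__(self):
        if not (self.max_specific_conductance >= self.basal_specific_conductance >= 0):
            raise ValueError("require max >= basal >= 0 specific conductance")
        if self.gating_charge <= 0:
            raise ValueError("gating charge must be positive")
        if self.activation_time_constant <= 0:
            raise ValueError("activation time constant must be positive")
        if self.protoplast_diameter <= 0:
            raise ValueError("protoplast diameter must be positive")
        if self.current_noise_sd < 0:
            raise ValueError("current noise sd must be non-negative")


#: Bundle-sheath group-mean channel parameters (diameter 27.4 um).
BSC_CHANNEL_PARAMS = ChannelModelParams(
    basal_specific_conductance=0.8, max_specific_conductance=1.75,
    half_activation_voltage=14.5, gating_charge=1.46,
    reversal_potential=-31.0, protoplast_diameter=27.4,
)

#: Mesophyll group-mean channel parameters (diameter 43.5 um).
MC_CHANNEL_PARAMS = ChannelModelParams(
    basal_specific_conductance=0.43, max_specific_conductance=1.15,
    half_activation_voltage=-6.5, gating_charge=1.03,
    reversal_potential=-31.0, protoplast_diameter=43.5,
)


def simulate_recording(
    params: ChannelModelParams,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    cell_type: str = "BSC",
    protoplast_id: str | None = None,
    bath: str = "low-K",
    gate_init: str = "holding",
    temperature_k: float = DEFAULT_TEMPERATURE_K,
) -> CurrentRecording:
    """Simulate one whole-cell recording under the pulse+ramp protocol.

    The open fraction p relaxes first-order (time constant tau) toward the
    Boltzmann steady state at the true pulse potential and is *frozen* at
    its pulse-end value during the brief testing ramp.  Total current is

        I = area * [G'_b + (G'_max - G'_b) * p] * (E - E_rev) + noise

    with E the true (LJP-corrected) potential; the stored command voltages
    are nominal, so the analysis side must re-apply the correction.

    ``gate_init`` — "holding": p starts each sweep at the steady state of
    the (corrected) holding potential, i.e. the gate re-equilibrates
    between sweeps; "steady": p starts at the steady state of the pulse
    potential itself (no relaxation transient).
    """
    if protocol is None:
        protocol = ProtocolSpec()
    if gate_init not in ("holding", "steady"):
        raise ValueError(f"unknown gate_init {gate_init!r}")
    rng = np.random.default_rng(seed)
    area = sphere_surface_area_cm2(params.protoplast_diameter)
    g_b = params.basal_specific_conductance
    g_net = params.max_specific_conductance - g_b
    tau = params.activation_time_constant

    def p_inf(e_true):
        return gate_open_probability(
            e_true, params.half_activation_voltage, params.gating_charge,
            temperature_k,
        )

    # mS * mV = 1e-6 A = uA -> pA
    def current_pa(g_specific, e_true):
        return area * g_specific * (e_true - params.reversal_potential) * 1e6

    fs = protocol.sampling_rate_hz
    n_pulse = protocol.n_pulse_samples
    n_ramp = protocol.n_ramp_samples
    t_pulse = np.arange(n_pulse) / fs * 1000.0  # ms from pulse onset
    ramp_v_nom = protocol.ramp_voltages()
    hold_true = protocol.holding_mv + protocol.ljp_mv

    frames = []
    flags = []
    if protocol.ramp_duration_ms >= tau:
        flags.append("ramp_slower_than_gate")
    for k, level in enumerate(protocol.pulse_levels):
        e_true = level + protocol.ljp_mv
        pinf = float(p_inf(e_true))
        p0 = float(p_inf(hold_true)) if gate_init == "holding" else pinf
        p_t = pinf + (p0 - pinf) * np.exp(-t_pulse / tau)
        g_t = g_b + g_net * p_t
        i_pulse = current_pa(g_t, e_true)
        p_end = p_t[-1] if n_pulse else p0
        g_frozen = g_b + g_net * p_end
        i_ramp = current_pa(g_frozen, ramp_v_nom + protocol.ljp_mv)
        i_all = np.concatenate([i_pulse, i_ramp])
        if params.current_noise_sd > 0:
            i_all = i_all + rng.normal(0.0, params.current_noise_sd, i_all.size)
        frames.append(pd.DataFrame({
            "time_ms": np.arange(n_pulse + n_ramp) / fs * 1000.0,
            "command_mv_nominal": np.concatenate(
                [np.full(n_pulse, float(level)), ramp_v_nom]
            ),
            "current_pa": i_all,
            "sweep_index": k,
        }))
    data = pd.concat(frames, ignore_index=True)
    if protoplast_id is None:
        protoplast_id = f"{cell_type}_sim{seed}"
    truth = {
        "basal_specific_conductance": g_b,
        "max_specific_conductance": params.max_specific_conductance,
        "half_activation_voltage": params.half_activation_voltage,
        "gating_charge": params.gating_charge,
        "reversal_potential": params.reversal_potential,
        "activation_time_constant": tau,
    }
    return CurrentRecording(
        protoplast_id=protoplast_id, diameter_um=params.protoplast_diameter,
        cell_type=cell_type, bath=bath, protocol=protocol, data=data,
        flags=flags, truth=truth,
    )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimSpec:
    """Design of a two-cell-type replicated log2 expression matrix.

    Per-gene baselines are drawn once from N(baseline_mean, baseline_sd);
    replicate measurements add N(0, noise_sd).  Genes listed in
    ``de_gene_indices`` are shifted by their true log2 fold-change in the
    first cell type (positive = higher in ``cell_types[0]``).
    """

    n_genes: int = 1000
    n_replicates_per_type: int = 3
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.2
    de_gene_indices: tuple = ()
    de_log2_fold_changes: tuple = ()
    cell_types: tuple = ("BSC", "MC")
    n_categories: int = 8
    transporter_fraction: float = 0.07
    seed: int = 0

    def __post_init__(self):
        idx = tuple(int(i) for i in self.de_gene_indices)
        if len(set(idx)) != len(idx):
            raise ValueError("de_gene_indices must be unique")
        if idx and (min(idx) < 0 or max(idx) >= self.n_genes):
            raise ValueError("de_gene_indices out of range")
        if len(idx) != len(tuple(self.de_log2_fold_changes)):
            raise ValueError("one fold change required per DE gene")
        if self.n_replicates_per_type < 2:
            raise ValueError("need >= 2 replicates per cell type")
        if len(self.cell_types) != 2:
            raise ValueError("exactly two cell types")
        self.de_gene_indices = idx
        self.de_log2_fold_changes = tuple(float(f) for f in self.de_log2_fold_changes)


def simulate_expression_matrix(spec: ExpressionSimSpec):
    """Generate the matrix and its truth table.

    Returns ``(matrix, truth)`` where ``matrix`` is a
    :class:`leafphys.transcriptome.ExpressionMatrix` (values, sample cell
    types, gene annotations) and ``truth`` a per-gene DataFrame with the
    is_de flag, true log2 fold change, category label and transporter flag.
    """
    from .transcriptome import ExpressionMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    type_a, type_b = spec.cell_types
    samples = [f"{type_a}_rep{r + 1}" for r in range(spec.n_replicates_per_type)] + \
              [f"{type_b}_rep{r + 1}" for r in range(spec.n_replicates_per_type)]
    sample_types = pd.Series(
        [type_a] * spec.n_replicates_per_type + [type_b] * spec.n_replicates_per_type,
        index=samples,
    )
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    shift = np.zeros(spec.n_genes)
    for i, fc in zip(spec.de_gene_indices, spec.de_log2_fold_changes):
        shift[i] = fc
    n_rep = spec.n_replicates_per_type
    means = np.hstack(
        [np.tile((baseline + shift)[:, None], (1, n_rep)),
         np.tile(baseline[:, None], (1, n_rep))]
    )
    values = means + rng.normal(0.0, spec.noise_sd, means.shape)
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)

    categories = np.array(
        [f"CAT{rng.integers(spec.n_categories):02d}" for _ in range(spec.n_genes)]
    )
    transporter = rng.random(spec.n_genes) < spec.transporter_fraction
    annotations = pd.DataFrame({
        "gene_id": genes,
        "category": categories,
        "transporter": transporter.astype(int),
    }).set_index("gene_id")

    is_de = np.zeros(spec.n_genes, dtype=bool)
    is_de[list(spec.de_gene_indices)] = True
    truth = pd.DataFrame({
        "gene_id": genes,
        "is_de": is_de,
        "true_log2_fc": shift,
        "category": categories,
        "transporter": transporter,
    }).set_index("gene_id")
    matrix = ExpressionMatrix(data=data, sample_types=sample_types,
                              annotations=annotations)
    return matrix, truth


# ---------------------------------------------------------------------------
# ratiometric image pairs
# ---------------------------------------------------------------------------

@dataclass
class RatioImageSpec:
    """Design of a dual-excitation protoplast field.

    Each protoplast is a membrane ring.  The 531 nm-excitation ring
    amplitude is fixed; the 438 nm amplitude is scaled so the
    background-subtracted ratio 438/531 equals
    ``ratio_intercept + ratio_slope * potential`` for that cell
    (slope > 0, so a more negative potential gives a smaller ratio).
    """

    shape: tuple = (256, 256)
    centers: tuple = ((128, 128),)
    radii: tuple = (20.0,)
    potentials_mv: tuple = (-100.0,)
    group_labels: tuple | None = None
    ratio_intercept: float = 1.8
    ratio_slope: float = 0.01  # per mV
    ring_thickness: float = 3.0
    amplitude_531: float = 20000.0
    background: float = 500.0
    noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self):
        n = len(self.centers)
        if not (len(self.radii) == len(self.potentials_mv) == n):
            raise ValueError("centers, radii and potentials must align")
        if self.group_labels is not None and len(self.group_labels) != n:
            raise ValueError("group_labels must align with centers")
        if self.ratio_slope <= 0:
            raise ValueError(
                "ratio_slope must be positive (more negative potential -> smaller ratio)"
            )
        for (i, j) in ((i, j) for i in range(n) for j in range(i + 1, n)):
            (r0, c0), (r1, c1) = self.centers[i], self.centers[j]
            d = np.hypot(r0 - r1, c0 - c1)
            if d <= self.radii[i] + self.radii[j] + 2 * self.ring_thickness:
                raise ValueError(f"protoplasts {i} and {j} overlap")
        for v in self.potentials_mv:
            if self.ratio_intercept + self.ratio_slope * v <= 0:
                raise ValueError(f"potential {v} mV maps to a non-positive ratio")


@dataclass
class RatioImagePair:
    """Registered 438 nm- and 531 nm-excitation images (uint16) + truth."""

    image_438: np.ndarray
    image_531: np.ndarray
    truth: pd.DataFrame  # per protoplast: center, radius, potential, true ratio


def simulate_ratio_images(spec: RatioImageSpec) -> RatioImagePair:
    """Render the field and return both channels with the truth table."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w]
    im531 = np.full(spec.shape, spec.background, dtype=float)
    im438 = np.full(spec.shape, spec.background, dtype=float)
    records = []
    for k, ((r0, c0), rad, pot) in enumerate(
        zip(spec.centers, spec.radii, spec.potentials_mv)
    ):
        ratio = spec.ratio_intercept + spec.ratio_slope * pot
        dist = np.hypot(rr - r0, cc - c0)
        ring = np.abs(dist - rad) <= spec.ring_thickness / 2.0
        im531[ring] += spec.amplitude_531
        im438[ring] += spec.amplitude_531 * ratio
        records.append({
            "protoplast": k, "center_row": r0, "center_col": c0,
            "radius_px": rad, "potential_mv": pot, "true_ratio": ratio,
            "group": spec.group_labels[k] if spec.group_labels else "all",
        })
    if spec.noise_sd > 0:
        im531 = im531 + rng.normal(0.0, spec.noise_sd, spec.shape)
        im438 = im438 + rng.normal(0.0, spec.noise_sd, spec.shape)
    to_u16 = lambda im: np.clip(np.rint(im), 0, 65535).astype(np.uint16)
    return RatioImagePair(
        image_438=to_u16(im438), image_531=to_u16(im531),
        truth=pd.DataFrame(records).set_index("protoplast"),
    )
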