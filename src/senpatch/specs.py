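"""Validated parameter records for every synthetic-data generator.

Each spec is a frozen dataclass whose defaults encode the study conditions
the pipeline is exercised under: a 197-cell patch-seq cohort with a 13.7%
senescence-marker-high pyramidal cluster (PY2), fast-spiking versus
regular-spiking intrinsic phenotypes, and a two-class EASI-FISH population
(PY2 fraction 2369/7688) imaged at 2x physical expansion with
0.23 x 0.23 x 0.4 um post-expansion voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Six genes quantified per neuron in the FISH experiment.
FISH_GENES = ("NFKBIA", "CDKN1A", "CCL2", "CUX2", "NEFM", "NEFH")

#: Post-expansion voxel size in um, (z, y, x) order.
DEFAULT_VOXEL_UM = (0.4, 0.23, 0.23)


@dataclass(frozen=True)
class EphysSimSpec:
    """Ground-truth membrane and action-potential parameters for one cell.

    ``rheobase_pA`` is the smallest step current that elicits a spike; the
    passive membrane obeys a single-exponential RC response with time
    constant ``tau = rin_MOhm * cm_pF`` (ms when expressed in MOhm x nF).
    ``adaptation_ratio`` is the asymptotic last/first inter-spike-interval
    ratio of the adapting spike-time model.
    """

    cell_class: str = "regular_spiking"
    rmp_mV: float = -65.0
    rin_MOhm: float = 150.0
    cm_pF: float = 120.0
    ap_threshold_mV: float = -40.0
    ap_amp_mV: float = 85.0
    ahp_mV: float = 8.0
    rheobase_pA: float = 120.0
    adaptation_ratio: float = 2.0
    ap_halfwidth_ms: float = 1.0
    fi_gain_hz_per_pa: float = 0.25
    noise_sd_mV: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.cell_class not in ("fast_spiking", "regular_spiking"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        for name in ("rin_MOhm", "cm_pF", "rheobase_pA", "ap_halfwidth_ms",
                     "adaptation_ratio", "fi_gain_hz_per_pa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_mV < 0:
            raise ValueError("noise_sd_mV must be non-negative")
        if self.ap_amp_mV <= 0 or self.ahp_mV < 0:
            raise ValueError("AP amplitude must be positive and AHP non-negative")

    @property
    def tau_ms(self) -> float:
        # MOhm * pF = us; divide by 1000 for ms
        return self.rin_MOhm * self.cm_pF / 1000.0

    @classmethod
    def fast_spiking(cls, seed: int = 0, **overrides) -> "EphysSimSpec":
        """Interneuron-like defaults: high Rin, small Cm, deep AHP, no adaptation."""
        kw = dict(cell_class="fast_spiking", rmp_mV=-67.0, rin_MOhm=250.0,
                  cm_pF=60.0, ap_threshold_mV=-42.0, ap_amp_mV=70.0, ahp_mV=18.0,
                  rheobase_pA=80.0, adaptation_ratio=1.1, ap_halfwidth_ms=0.5,
                  fi_gain_hz_per_pa=0.7, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def regular_spiking(cls, seed: int = 0, **overrides) -> "EphysSimSpec":
        """Pyramidal-like defaults: lower Rin, larger Cm, shallow AHP, strong adaptation."""
        kw = dict(cell_class="regular_spiking", seed=seed)
        kw.update(overrides)
        return cls(**kw)


def _default_cluster_cells() -> dict:
    # 197 patch-seq neurons: 53 interneurons and 144 pyramidal cells of which
    # 27 (13.7% of total, 18.8% of pyramidal) form the senescence-high PY2 cluster.
    return {"INT": 53, "PY1": 90, "PY2": 27, "PY3": 27}


def _default_markers() -> dict:
    # log2 fold-changes of planted one-vs-rest cluster markers
    sasp = ["IL1A", "IL1B", "CCL4", "CCL2", "CXCL8", "CXCL12", "MMP2",
            "CTSB", "ICAM1", "TNFRSF1B", "TNFRSF12A"]
    senescence = ["CDKN1A", "TP53", "NFKBIA", "GLB1", "PTGS2", "H2AX"]
    py2 = {g: 2.0 for g in senescence + sasp
           + ["NEFM", "NEFH", "RPS6", "RHEB", "EIF4E"]}
    py2["LMNB1"] = -1.0  # nuclear-lamina loss is part of the senescent phenotype
    return {
        "INT": {g: 3.0 for g in ["GAD1", "GAD2", "ERBB4", "DLX1", "LHX6"]},
        "PY1": {g: 2.0 for g in ["LAMP5", "RORB", "THEMIS"]},
        "PY2": py2,
        "PY3": {g: 2.0 for g in ["NR4A2", "CRYM", "PCP4"]},
    }


def _default_class_markers() -> dict:
    # pan-class programs shared by several clusters (pyramidal identity genes)
    return {("PY1", "PY2", "PY3"): {g: 3.0 for g in ["SATB2", "CUX2", "SLC17A6", "SLC17A7"]}}


@dataclass(frozen=True)
class ExprSimSpec:
    """Four-cluster patch-seq count-matrix generator parameters.

    Counts follow a minimal hierarchical model: per-gene baseline expression,
    cluster fold-changes on planted markers, a per-donor log-normal random
    effect, log-normal library sizes, Poisson sampling and Bernoulli dropout.
    ERCC spike-in rows are drawn independently of the cluster label.
    """

    cluster_cells: dict = field(default_factory=_default_cluster_cells)
    n_genes: int = 2000
    n_ercc: int = 92
    markers: dict = field(default_factory=_default_markers)
    class_markers: dict = field(default_factory=_default_class_markers)
    dropout_rate: float = 0.2
    #: expected-count scale on which dropout decays: a measurement with
    #: expected count lam survives with probability
    #: (1 - dropout_rate) ** exp(-lam / dropout_decay), so dropout
    #: concentrates on lowly expressed genes and dropout_rate is the
    #: zero-expression dropout probability
    dropout_decay: float = 1.0
    n_donors: int = 6
    donor_sd: float = 0.05
    library_size_mean: float = 20000.0
    library_size_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not self.cluster_cells or any(n <= 0 for n in self.cluster_cells.values()):
            raise ValueError("every cluster must contain at least one cell")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        named = {g for d in self.markers.values() for g in d}
        named |= {g for d in self.class_markers.values() for g in d}
        if self.n_genes < len(named):
            raise ValueError("n_genes smaller than the number of named marker genes")
        for d in list(self.markers.values()) + list(self.class_markers.values()):
            if any(2.0 ** lfc <= 0 for lfc in d.values()):
                raise ValueError("fold-changes must be positive")
        if self.library_size_mean <= 0 or self.n_donors < 1:
            raise ValueError("library_size_mean must be positive and n_donors >= 1")

    @property
    def n_cells(self) -> int:
        return int(sum(self.cluster_cells.values()))


def _default_densities() -> dict:
    # spots per um^3 of pre-expansion soma volume, per molecular class;
    # PY2 carries higher NFKBIA/CDKN1A/CCL2/NEFM/NEFH density, CUX2 near-equal
    py1 = {"NFKBIA": 0.05, "CDKN1A": 0.03, "CCL2": 0.012, "CUX2": 0.08,
           "NEFM": 0.06, "NEFH": 0.04}
    py2 = {g: (v * 1.1 if g == "CUX2" else v * 2.5) for g, v in py1.items()}
    return {"PY1": py1, "PY2": py2}


@dataclass(frozen=True)
class FishSimSpec:
    """Two-class EASI-FISH sample generator parameters.

    Somas are axis-aligned ellipsoids (analytic ground-truth volume); the PY2
    class is stochastically larger. Per-cell expected transcript count is
    density x pre-expansion soma volume; coordinates are emitted on the
    post-expansion scale used at the microscope.
    """

    n_cells: int = 300
    fraction_py2: float = 2369 / 7688
    #: mean ellipsoid semi-axes (z, y, x) in pre-expansion um, per class
    soma_axes_um: dict = field(default_factory=lambda: {
        "PY1": (4.5, 5.0, 5.5), "PY2": (5.6, 6.2, 6.8)})
    soma_sd_log: float = 0.08
    densities: dict = field(default_factory=_default_densities)
    expansion_factor: float = 2.0
    voxel_um: tuple = DEFAULT_VOXEL_UM
    background_spots_per_um3: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fraction_py2 < 1:
            raise ValueError("fraction_py2 must lie strictly inside (0, 1)")
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel dimensions must be positive")
        for cls_d in self.densities.values():
            if any(d < 0 for d in cls_d.values()):
                raise ValueError("densities must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def genes(self) -> tuple:
        return tuple(next(iter(self.densities.values())).keys())


@dataclass(frozen=True)
class HistoSimSpec:
    """Marker-positivity count generator for SMI+ vs SMI- neuron tables."""

    n_samples: int = 5
    n_per_class: dict = field(default_factory=lambda: {"SMI+": 40, "SMI-": 160})
    p_marker: dict = field(default_factory=lambda: {"SMI+": 0.75, "SMI-": 0.10})
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if set(self.n_per_class) != set(self.p_marker):
            raise ValueError("n_per_class and p_marker must name the same classes")
        if any(not 0 <= p <= 1 for p in self.p_marker.values()):
            raise ValueError("marker probabilities must lie in [0, 1]")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 1")


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Two-arm exponential survival generator with administrative censoring."""

    n_a: int = 18
    n_b: int = 10
    hazard_a: float = 0.04
    hazard_b: float = 0.01
    censor_time: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.hazard_a <= 0 or self.hazard_b <= 0:
            raise ValueError("hazards must be positive")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("arm sizes must be >= 1")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
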