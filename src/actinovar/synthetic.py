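"""Synthetic fixtures with known ground truth for every pipeline stage.

Generators emulate the data of a toxin-family variability study: a sequence
family evolving under role-dependent purifying pressure (a star phylogeny
whose per-site substitution probability depends on whether the site is a
lipid-binding residue, a protomer–protomer interface residue, or a buried or
exposed non-interacting residue), toy atomic structures with controlled
burial, sigmoidal hemolysis turbidity traces with a defined lag phase,
Hill dose–response tables, and two-state thermal melting curves.

All generators are seeded and bit-reproducible, and emit their ground truth
alongside the data so recovery can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .conservation import Alignment
from .crosstab import Role
from .kinetics import HemolysisTrace
from .melting import MeltingCurve
from .sequences import Alphabet, SequenceRecord
from .structure import ASAClass, ASAEntry

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Default family conditions: 17 family members, a 175-residue mature chain,
# ~73% non-interacting positions, and per-role substitution probabilities
# chosen so that ~56% of lipid-binding and ~25% of interface columns stay
# strictly identical across 17 sequences, the buried core is strongly
# conserved, and exposed non-interacting sites vary freely.
DEFAULT_ROLE_FRACTIONS = {"lipid": 0.13, "ppi": 0.14, "none": 0.73}
DEFAULT_SUB_PROBS = {"ppi": 0.078, "lipid": 0.034,
                     "none_buried": 0.02, "none_exposed": 0.15}
DEFAULT_BURIED_FRACTION = 0.40


@dataclass(frozen=True)
class FamilySpec:
    length: int = 175
    n_sequences: int = 17
    sub_probs: dict = field(default_factory=lambda: dict(DEFAULT_SUB_PROBS))
    role_fractions: dict = field(default_factory=lambda: dict(DEFAULT_ROLE_FRACTIONS))
    buried_fraction: float = DEFAULT_BURIED_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.sub_probs.values()):
            raise ValueError("substitution probabilities must lie in [0, 1]")
        if abs(sum(self.role_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("role fractions must sum to 1")
        if self.length < 1 or self.n_sequences < 2:
            raise ValueError("need length ≥1 and ≥2 sequences")


@dataclass(frozen=True)
class FamilyTruth:
    alignment: Alignment
    roles: dict[int, Role]
    exposure: dict[int, str]          # position -> "buried" | "exposed"
    site_class: dict[int, str]        # position -> sub_probs key
    ancestor: str


@dataclass(frozen=True)
class TraceSpec:
    lag: float = 13.0                 # s
    rate: float = 0.05                # max descent of A/A0, s⁻¹
    initial: float = 0.6              # A700 of the intact suspension
    final: float = 0.05
    noise_sd: float = 0.0             # absolute absorbance units
    dt: float = 0.5                   # s
    duration: float = 120.0           # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag < 0 or self.initial <= self.final:
            raise ValueError("need lag ≥0 and initial > final turbidity")


@dataclass(frozen=True)
class MeltSpec:
    tm: float = 53.0                  # °C
    dh: float = 300.0                 # van 't Hoff ΔH, kJ/mol
    t_min: float = 10.0
    t_max: float = 90.0
    dt: float = 0.1                   # °C sampling step (~1 °C/min scan)
    folded_baseline: tuple[float, float] = (-20.0, 0.02)   # intercept, slope
    unfolded_baseline: tuple[float, float] = (-4.0, 0.01)
    noise_sd: float = 0.0             # in signal units
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_min < self.tm < self.t_max):
            raise ValueError("tm must lie inside the simulated temperature range")


def generate_family(spec: FamilySpec) -> FamilyTruth:
    """Simulate a sequence family under role-dependent purifying pressure.

    A uniform-random ancestor is mutated independently in each descendant
    (star phylogeny): site i mutates with the probability of its role class,
    and substitutions are uniform over the 19 alternative residues. The truth
    tables (role, exposure, effective class) are returned with the alignment.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    ancestor = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    role_names = list(spec.role_fractions)
    role_draw = rng.choice(role_names, size=L, p=[spec.role_fractions[r] for r in role_names])
    roles: dict[int, Role] = {}
    exposure: dict[int, str] = {}
    site_class: dict[int, str] = {}
    for i in range(L):
        pos = i + 1
        role = Role(role_draw[i])
        roles[pos] = role
        if role is Role.NONE:
            buried = rng.random() < spec.buried_fraction
            exposure[pos] = "buried" if buried else "exposed"
            site_class[pos] = "none_buried" if buried else "none_exposed"
        else:
            # interacting residues sit at interfaces: partially buried
            exposure[pos] = "buried"
            site_class[pos] = role.value
    rows = []
    for s in range(spec.n_sequences):
        seq = list(ancestor)
        for i in range(L):
            p = spec.sub_probs[site_class[i + 1]]
            if p > 0 and rng.random() < p:
                alternatives = AMINO_ACIDS.replace(seq[i], "")
                seq[i] = alternatives[rng.integers(len(alternatives))]
        rows.append(SequenceRecord(id=f"syn{s:02d}", seq="".join(seq),
                                   alphabet=Alphabet.PROTEIN))
    return FamilyTruth(alignment=Alignment(rows=tuple(rows)), roles=roles,
                       exposure=exposure, site_class=site_class, ancestor=ancestor)


def asa_entries_from_exposure(exposure: dict[int, str], seed: int = 0,
                              chain: str = "A") -> list[ASAEntry]:
    """Per-position ASA entries consistent with a truth exposure map.

    Buried positions get side-chain ratios in the low band (<0.2), exposed
    positions in the high band (>0.5); used to exercise the cross-tab join
    without building a full structure per family.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for pos in sorted(exposure):
        if exposure[pos] == "buried":
            ratio = float(rng.uniform(0.0, 0.15))
            cls = ASAClass.LOW
        else:
            ratio = float(rng.uniform(0.55, 1.0))
            cls = ASAClass.HIGH
        entries.append(ASAEntry(chain=chain, residue_number=pos, residue_name="XXX",
                                sidechain_asa=ratio * 100.0, ratio=ratio, asa_class=cls))
    return entries


def generate_toy_structure(kind: str, residue_type: str = "ALA") -> list[geometry.AtomRecord]:
    """Toy structures with known burial: isolated or shell-buried residues,
    the extended Gly-X-Gly coil reference, or a short helix."""
    if kind == "isolated_residue":
        return geometry.build_gxg(residue_type)
    if kind == "buried_residue":
        res = geometry.build_residue(residue_type)
        center = np.array([a.xyz for a in res]).mean(axis=0)
        # two concentric layers leave no probe-sized gap anywhere around the residue
        shell = (geometry.build_shell(center, radius=4.5, n_atoms=350, serial0=10000)
                 + geometry.build_shell(center, radius=6.5, n_atoms=500, serial0=20000))
        return res + shell
    if kind == "extended_tripeptide":
        return geometry.build_gxg(residue_type)
    if kind == "helix":
        return geometry.build_helix(residue_type)
    raise ValueError(f"unknown toy-structure kind {kind!r}")


def generate_trace(spec: TraceSpec) -> HemolysisTrace:
    """Sigmoidal turbidity trace with a defined lag time and maximum rate.

    The descent is a compact-support sigmoid (cubic smoothstep): turbidity is
    exactly ``initial`` before onset, the maximum descent rate of A/A0 equals
    ``rate``, and the steepest tangent extended back to the initial level
    crosses it exactly ``lag`` seconds after time zero. A zero rate yields a
    flat (non-lysing) trace.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    if spec.rate <= 0:
        a = np.full_like(t, spec.initial)
    else:
        amplitude = spec.initial - spec.final
        # smoothstep 3u²-2u³ over duration T: max slope 1.5·ΔA/T at u=1/2,
        # steepest tangent meets the initial level at t_on + T/6
        T = 1.5 * amplitude / (spec.initial * spec.rate)
        t_on = spec.lag - T / 6.0
        u = np.clip((t - t_on) / T, 0.0, 1.0)
        a = spec.initial - amplitude * (3.0 * u ** 2 - 2.0 * u ** 3)
    if spec.noise_sd > 0:
        a = a + rng.normal(0.0, spec.noise_sd, size=t.size)
    return HemolysisTrace(time=t, absorbance=a)


def generate_dose_response(hc50: float, hill_n: float, concentrations,
                           noise_sd: float = 0.0, seed: int = 0,
                           plateau: float = 100.0) -> np.ndarray:
    """(conc, percent-hemolysis) table from a Hill curve plus Gaussian noise."""
    if hc50 <= 0 or hill_n <= 0:
        raise ValueError("hc50 and hill_n must be positive")
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    h = plateau * c ** hill_n / (hc50 ** hill_n + c ** hill_n)
    if noise_sd > 0:
        h = h + rng.normal(0.0, noise_sd, size=c.size)
    return np.column_stack([c, h])


def generate_melt(spec: MeltSpec) -> MeltingCurve:
    """Two-state thermal melt with linear folded/unfolded baselines.

    The unfolding equilibrium constant follows the van 't Hoff relation
    K(T) = exp[(ΔH/R)(1/Tm − 1/T)] with temperatures in kelvin, so exactly
    half the protein is unfolded at Tm.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.t_min, spec.t_max + spec.dt / 2, spec.dt)
    tk = t + 273.15
    tmk = spec.tm + 273.15
    R = 8.314462618e-3  # kJ/(mol·K)
    K = np.exp((spec.dh / R) * (1.0 / tmk - 1.0 / tk))
    fu = K / (1.0 + K)
    theta_n = spec.folded_baseline[0] + spec.folded_baseline[1] * t
    theta_u = spec.unfolded_baseline[0] + spec.unfolded_baseline[1] * t
    s = theta_n * (1.0 - fu) + theta_u * fu
    if spec.noise_sd > 0:
        s = s + rng.normal(0.0, spec.noise_sd, size=t.size)
    return MeltingCurve(temperature=t, signal=s)
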