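"""Coarse-grained generator for 12-base-pair RNA duplex bead models.

Each duplex is built from a :class:`HelicalParameterSet` — a helical radius,
eleven per-step twist/rise values and eleven binary step-form flags
(A-like vs compact) — on an ideal helical axis, then optionally perturbed
by per-bead Gaussian jitter.  Every residue contributes three beads
(phosphate, sugar, base) carrying summed electron counts, which is all the
downstream Debye scattering calculation needs at q <= 0.95 1/A
(real-space resolution ~ 2*pi/q ~ 6.6 A).

Geometry conventions
--------------------
The duplex axis is z; base pair ``i`` sits at height ``z_i = sum(rise[:i])``
and frame azimuth ``phi_i = sum(twist[:i])``.  Phosphate beads of the two
antiparallel strands lead the base-pair frame azimuth by
``+BACKBONE_LEAD * mean_twist`` and ``STRAND_PHASE_DEG - BACKBONE_LEAD *
mean_twist`` respectively: the phosphate bridges adjacent residues, so its
azimuth advances along each strand's own chain direction.  The two
constants are calibrated jointly so that (a) the canonical A-form duplex
reproduces the 8.7 A major-groove width used as the geometric calibration
point and (b) unwinding the duplex narrows the major groove while
over-winding widens it, the behaviour reported for dsRNA in solution.

Base beads are displaced from the axis into the wide inter-backbone gap;
A-like steps use the larger A-form displacement, compact (non-A) steps a
small one, so the A-form fraction has visible consequences in scattering.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_BP = 12
N_STEPS = N_BP - 1
BEADS_PER_RESIDUE = 3
N_BEADS = 2 * N_BP * BEADS_PER_RESIDUE  # 72

DEFAULT_SEQUENCE = ("CCUCCUAAUCGC", "GCGAUUAGGAGG")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Strand-phase constant and backbone lead factor (see module docstring).
STRAND_PHASE_DEG = 406.043
BACKBONE_LEAD = 2.5
# Sugar beads sit this far inside the phosphate radius.
SUGAR_INSET = 2.9
# Azimuthal half-split between the two base beads of one pair.
BASE_SPLIT_DEG = 10.0


@dataclass(frozen=True)
class StepSetpoints:
    """Twist (deg), rise (A) and base displacement (A) of one step class."""

    twist: float
    rise: float
    displacement: float


#: Ensemble setpoints for A-like steps.
A_STEP = StepSetpoints(twist=32.7, rise=2.70, displacement=4.0)
#: Ensemble setpoints for compact (non-A) steps: unwound, axially
#: compressed, bases pulled toward the axis.
COMPACT_STEP = StepSetpoints(twist=28.0, rise=2.33, displacement=1.5)
#: Fiber-model canonical A-RNA: 11 bp/turn, 2.81 A rise, phosphates 9.4 A
#: from the axis.
CANONICAL_A = StepSetpoints(twist=32.7, rise=2.81, displacement=4.4)
CANONICAL_RADIUS = 9.4

# Electron counts per bead, by summed atomic numbers of the assigned atoms.
#   phosphate: P + O1P + O2P + O3' + O5'          = 15 + 4*8        = 47
#   sugar:     C1'..C5' + O4' + O2' + 7 H         = 5*6 + 2*8 + 7   = 53
#   base (glycosidic H lost):
#     A  C5H4N5   = 30 + 4 + 35      = 69
#     G  C5H4N5O  = 30 + 4 + 35 + 8  = 77
#     C  C4H4N3O  = 24 + 4 + 21 + 8  = 57
#     U  C4H3N2O2 = 24 + 3 + 14 + 16 = 57
# Terminal-residue chemistry (missing 5' phosphate) is deliberately not
# modelled so that all conformations of a sequence carry identical totals.
PHOSPHATE_ELECTRONS = 47
SUGAR_ELECTRONS = 53
BASE_ELECTRONS = {"A": 69, "G": 77, "C": 57, "U": 57}

BEAD_KINDS = ("phosphate", "sugar", "base")


class DuplexError(ValueError):
    """Invalid duplex parameters or sequence."""


def complement(strand: str) -> str:
    """Watson-Crick complement of an RNA strand, returned 5'->3'."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(strand.upper()))
    except KeyError as exc:
        raise DuplexError(f"non-RNA base {exc.args[0]!r} in sequence") from None


def _check_sequence(sequence: Sequence[str]) -> tuple[str, str]:
    s1, s2 = (s.upper() for s in sequence)
    if len(s1) != N_BP or len(s2) != N_BP:
        raise DuplexError(
            f"strands must be {N_BP} nt, got {len(s1)} and {len(s2)}"
        )
    if complement(s1) != s2:
        raise DuplexError("strands are not complementary")
    return s1, s2


@dataclass(frozen=True)
class HelicalParameterSet:
    """Latent generator parameters of one duplex conformation.

    Parameters
    ----------
    radius : float
        Distance of the phosphate beads from the helical axis, in A.
    step_twist, step_rise : sequence of 11 floats
        Per-base-pair-step rotation (deg) and translation (A).
    step_form : sequence of 11 bools
        ``True`` for A-like steps, ``False`` for compact steps.
    jitter_scale : float
        Standard deviation of the isotropic Gaussian positional noise
        applied to every bead, in A.
    """

    conformation_id: str
    radius: float
    step_twist: tuple[float, ...]
    step_rise: tuple[float, ...]
    step_form: tuple[bool, ...]
    jitter_scale: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "step_twist", tuple(float(t) for t in self.step_twist))
        object.__setattr__(self, "step_rise", tuple(float(r) for r in self.step_rise))
        object.__setattr__(self, "step_form", tuple(bool(f) for f in self.step_form))
        for name in ("step_twist", "step_rise", "step_form"):
            if len(getattr(self, name)) != N_STEPS:
                raise DuplexError(
                    f"{name} needs {N_STEPS} entries for a {N_BP}-bp duplex, "
                    f"got {len(getattr(self, name))}"
                )
        if not self.radius > 0:
            raise DuplexError(f"radius must be positive, got {self.radius}")
        if any(r <= 0 for r in self.step_rise):
            raise DuplexError("all step rises must be positive")
        if any(not 0.0 < t < 60.0 for t in self.step_twist):
            raise DuplexError("step twists must lie in (0, 60) degrees")
        if self.jitter_scale < 0:
            raise DuplexError("jitter_scale must be non-negative")

    @property
    def aform_class(self) -> int:
        """Number of A-flagged steps, 0..11."""
        return int(sum(self.step_form))

    @property
    def mean_twist(self) -> float:
        return float(np.mean(self.step_twist))

    @property
    def mean_rise(self) -> float:
        return float(np.mean(self.step_rise))


@dataclass
class DuplexModel:
    """Coarse-grained bead model of one duplex conformation.

    Bead arrays run strand 1 residues 1..12 then strand 2 residues 1..12,
    three beads (phosphate, sugar, base) per residue.  ``latent_params``
    retains the generating :class:`HelicalParameterSet` for round-trip
    tests only; it is never used as a supervised label.
    """

    conformation_id: str
    sequence: tuple[str, str]
    strand: np.ndarray       # (72,) int, 1 or 2
    residue: np.ndarray      # (72,) int, 1..12 within its strand
    bead_kind: np.ndarray    # (72,) str
    coords: np.ndarray       # (72, 3) float, A
    electrons: np.ndarray    # (72,) float
    latent_params: HelicalParameterSet | None = None

    def __post_init__(self):
        if len(self.coords) != N_BEADS:
            raise DuplexError(f"expected {N_BEADS} beads, got {len(self.coords)}")
        if np.any(self.electrons <= 0):
            raise DuplexError("every bead must carry a positive electron count")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def total_electrons(self) -> float:
        return float(self.electrons.sum())

    def mask(self, kind: str, strand: int | None = None) -> np.ndarray:
        m = self.bead_kind == kind
        if strand is not None:
            m &= self.strand == strand
        return m

    def bp_index(self) -> np.ndarray:
        """Base-pair level (0..11) of every bead.

        Strand 2 residue ``k`` pairs with strand 1 residue ``13 - k``.
        """
        idx = self.residue - 1
        return np.where(self.strand == 1, idx, N_BP - 1 - idx)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "DuplexModel":
        """Rigid-body copy; descriptors and Debye profiles are invariant."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return replace_coords(self, coords)

    def max_distance(self) -> float:
        """Largest intramolecular bead-bead distance (D_max), in A."""
        from scipy.spatial.distance import pdist

        return float(pdist(self.coords).max())


def replace_coords(model: DuplexModel, coords: np.ndarray) -> DuplexModel:
    return DuplexModel(
        conformation_id=model.conformation_id,
        sequence=model.sequence,
        strand=model.strand.copy(),
        residue=model.residue.copy(),
        bead_kind=model.bead_kind.copy(),
        coords=np.array(coords, dtype=float),
        electrons=model.electrons.copy(),
        latent_params=model.latent_params,
    )


def build_duplex(
    params: HelicalParameterSet,
    sequence: Sequence[str] = DEFAULT_SEQUENCE,
    seed: int = 0,
    *,
    strand_phase_deg: float = STRAND_PHASE_DEG,
    backbone_lead: float = BACKBONE_LEAD,
    a_displacement: float | None = None,
    compact_displacement: float | None = None,
) -> DuplexModel:
    """Place the 72 beads of one duplex on an ideal helix and jitter them.

    Deterministic given ``(params, seed)``.  The residue-level base
    displacement follows the form flag of the step it opens (the last
    residue inherits the final step's flag).
    """
    s1, s2 = _check_sequence(sequence)
    d_a = A_STEP.displacement if a_displacement is None else a_displacement
    d_c = COMPACT_STEP.displacement if compact_displacement is None else compact_displacement

    twist = np.asarray(params.step_twist)
    rise = np.asarray(params.step_rise)
    phi = np.deg2rad(np.concatenate(([0.0], np.cumsum(twist))))
    z = np.concatenate(([0.0], np.cumsum(rise)))
    lead = np.deg2rad(backbone_lead * params.mean_twist)
    gamma0 = np.deg2rad(strand_phase_deg)
    split = np.deg2rad(BASE_SPLIT_DEG)

    # form flag per residue (bp level), shared by both strands of the pair
    form = np.array(params.step_form + (params.step_form[-1],))
    disp = np.where(form, d_a, d_c)

    strand = np.empty(N_BEADS, dtype=int)
    residue = np.empty(N_BEADS, dtype=int)
    bead_kind = np.empty(N_BEADS, dtype=object)
    coords = np.empty((N_BEADS, 3))
    electrons = np.empty(N_BEADS)

    def _place(az, rad, height):
        return np.array([rad * np.cos(az), rad * np.sin(az), height])

    k = 0
    for s, strand_seq in ((1, s1), (2, s2)):
        for res in range(1, N_BP + 1):
            i = res - 1 if s == 1 else N_BP - res  # bp level
            if s == 1:
                p_az = phi[i] + lead
                b_az = phi[i] + gamma0 / 2 - split
            else:
                p_az = phi[i] + gamma0 - lead
                b_az = phi[i] + gamma0 / 2 + split
            base = strand_seq[res - 1]
            for kind, az, rad in (
                ("phosphate", p_az, params.radius),
                ("sugar", p_az, params.radius - SUGAR_INSET),
                ("base", b_az, disp[i]),
            ):
                strand[k] = s
                residue[k] = res
                bead_kind[k] = kind
                coords[k] = _place(az, rad, z[i])
                electrons[k] = {
                    "phosphate": PHOSPHATE_ELECTRONS,
                    "sugar": SUGAR_ELECTRONS,
                    "base": BASE_ELECTRONS[base],
                }[kind]
                k += 1

    if params.jitter_scale > 0:
        rng = np.random.default_rng(_bead_seed(params.conformation_id, seed))
        coords = coords + rng.normal(0.0, params.jitter_scale, coords.shape)

    return DuplexModel(
        conformation_id=params.conformation_id,
        sequence=(s1, s2),
        strand=strand,
        residue=residue,
        bead_kind=bead_kind,
        coords=coords,
        electrons=electrons,
        latent_params=params,
    )


def _bead_seed(conformation_id: str, seed: int) -> int:
    h = hashlib.sha256(f"{conformation_id}:{seed}".encode()).digest()
    return int.from_bytes(h[:4], "little")


def canonical_aform(sequence: Sequence[str] = DEFAULT_SEQUENCE) -> DuplexModel:
    """Fiber-model canonical A-RNA duplex: the geometric calibration reference.

    Uniform twist/rise/radius, all steps A-flagged, zero jitter — invariant
    under re-invocation.
    """
    params = HelicalParameterSet(
        conformation_id="canonical_A",
        radius=CANONICAL_RADIUS,
        step_twist=(CANONICAL_A.twist,) * N_STEPS,
        step_rise=(CANONICAL_A.rise,) * N_STEPS,
        step_form=(True,) * N_STEPS,
        jitter_scale=0.0,
    )
    return build_duplex(
        params,
        sequence,
        a_displacement=CANONICAL_A.displacement,
    )


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling ranges of the synthetic ensemble (the study conditions).

    ``radius`` is drawn uniformly per conformation; per-step twist and rise
    are the step-class setpoint plus bounded uniform noise (bounded so that
    geometric step classification can never cross the A/compact midpoint on
    zero-jitter models); the per-conformation A-step propensity ``p`` is
    drawn uniformly from ``aform_propensity`` and step flags are Bernoulli(p),
    covering all 12 A-fraction classes.
    """

    radius: tuple[float, float] = (8.5, 10.5)
    twist_jitter: float = 2.0   # deg, uniform half-width; A/compact gap is 4.7
    rise_jitter: float = 0.12   # A, uniform half-width; A/compact gap is 0.37
    aform_propensity: tuple[float, float] = (0.0, 1.0)
    jitter_scale: float = 0.25  # A, per-bead Gaussian noise

    def __post_init__(self):
        for name in ("radius", "aform_propensity"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise DuplexError(f"degenerate range for {name}: {lo} > {hi}")
        if self.twist_jitter < 0 or self.rise_jitter < 0 or self.jitter_scale < 0:
            raise DuplexError("jitter amplitudes must be non-negative")
        if self.radius[0] <= 0:
            raise DuplexError("radius range must be positive")


def sample_parameter_set(
    rng: np.random.Generator,
    conformation_id: str,
    ranges: ParameterRanges = ParameterRanges(),
) -> HelicalParameterSet:
    """Draw the latent parameters of one conformation."""
    p = rng.uniform(*ranges.aform_propensity)
    form = rng.random(N_STEPS) < p
    twist = np.where(form, A_STEP.twist, COMPACT_STEP.twist) + rng.uniform(
        -ranges.twist_jitter, ranges.twist_jitter, N_STEPS
    )
    rise = np.where(form, A_STEP.rise, COMPACT_STEP.rise) + rng.uniform(
        -ranges.rise_jitter, ranges.rise_jitter, N_STEPS
    )
    return HelicalParameterSet(
        conformation_id=conformation_id,
        radius=float(rng.uniform(*ranges.radius)),
        step_twist=tuple(twist),
        step_rise=tuple(rise),
        step_form=tuple(form),
        jitter_scale=ranges.jitter_scale,
    )


def sample_ensemble(
    n: int,
    ranges: ParameterRanges = ParameterRanges(),
    seed: int = 0,
    sequence: Sequence[str] = DEFAULT_SEQUENCE,
) -> list[DuplexModel]:
    """Generate ``n`` independent duplex conformations, reproducibly."""
    if n < 1:
        raise DuplexError("ensemble size must be at least 1")
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        params = sample_parameter_set(rng, f"conf{i:06d}", ranges)
        models.append(build_duplex(params, sequence, seed=seed))
    return models


# ---------------------------------------------------------------------------
# PDB and manifest I/O

_KIND_TO_ATOM = {"phosphate": ("P", "P"), "sugar": ("SUG", "C"), "base": ("BAS", "N")}
_ATOM_TO_KIND = {"P": "phosphate", "SUG": "sugar", "BAS": "base"}


def write_pdb(model: DuplexModel, path: str | Path) -> None:
    """Write one pseudo-atom per bead; electron count in the B-factor column."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    atoms = struc.AtomArray(model.n_beads)
    atoms.coord = np.asarray(model.coords, dtype=np.float32)
    atoms.chain_id = np.where(model.strand == 1, "A", "B")
    atoms.res_id = model.residue
    seq_lookup = {1: model.sequence[0], 2: model.sequence[1]}
    atoms.res_name = np.array(
        [seq_lookup[s][r - 1] for s, r in zip(model.strand, model.residue)]
    )
    atoms.atom_name = np.array([_KIND_TO_ATOM[k][0] for k in model.bead_kind])
    atoms.element = np.array([_KIND_TO_ATOM[k][1] for k in model.bead_kind])
    atoms.hetero = np.full(model.n_beads, True)
    atoms.set_annotation("b_factor", model.electrons.astype(float))
    atoms.set_annotation("occupancy", np.ones(model.n_beads))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb(path: str | Path, conformation_id: str | None = None) -> DuplexModel:
    """Read a bead model written by :func:`write_pdb` (latent params are lost)."""
    from biotite.structure.io.pdb import PDBFile

    atoms = PDBFile.read(str(path)).get_structure(model=1, extra_fields=["b_factor"])
    strand = np.where(atoms.chain_id == "A", 1, 2)
    res_name = atoms.res_name
    s1 = "".join(res_name[(strand == 1)][::BEADS_PER_RESIDUE])
    s2 = "".join(res_name[(strand == 2)][::BEADS_PER_RESIDUE])
    return DuplexModel(
        conformation_id=conformation_id or Path(path).stem,
        sequence=(s1, s2),
        strand=strand,
        residue=atoms.res_id.astype(int),
        bead_kind=np.array([_ATOM_TO_KIND[a] for a in atoms.atom_name], dtype=object),
        coords=np.asarray(atoms.coord, dtype=float),
        electrons=np.asarray(atoms.b_factor, dtype=float),
    )


def write_manifest(models: Iterable[DuplexModel], path: str | Path,
                   pdb_paths: dict[str, str] | None = None) -> pd.DataFrame:
    """Columnar table of conformation ids, latent parameters and file paths."""
    rows = []
    for m in models:
        p = m.latent_params
        if p is None:
            raise DuplexError(
                f"model {m.conformation_id} has no latent parameters; "
                "manifests describe generated ensembles"
            )
        rows.append(
            {
                "conformation_id": m.conformation_id,
                "radius": p.radius,
                "mean_twist": p.mean_twist,
                "mean_rise": p.mean_rise,
                "aform_class": p.aform_class,
                "jitter_scale": p.jitter_scale,
                "step_twist": ";".join(f"{t:.17g}" for t in p.step_twist),
                "step_rise": ";".join(f"{r:.17g}" for r in p.step_rise),
                "step_form": "".join("A" if f else "c" for f in p.step_form),
                "pdb_path": (pdb_paths or {}).get(m.conformation_id, ""),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> list[HelicalParameterSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        out.append(
            HelicalParameterSet(
                conformation_id=str(row["conformation_id"]),
                radius=float(row["radius"]),
                step_twist=tuple(float(x) for x in str(row["step_twist"]).split(";")),
                step_rise=tuple(float(x) for x in str(row["step_rise"]).split(";")),
                step_form=tuple(ch == "A" for ch in str(row["step_form"])),
                jitter_scale=float(row["jitter_scale"]),
            )
        )
    return out
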