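"""Synthetic ground-truth generators for the occupancy and sequence pipelines.

Real inputs to this package come from a single-particle cryo-EM
pipeline (particle orientation tables, per-region occupancy
classifications) and from curated multiple sequence alignments.  Both
are emulated here with known ground truth so every downstream stage can
be tested end to end:

* cores with a planted number of CBD trimers at mutually compatible
  interior 3-fold sites, random orientations, and independent
  false-positive / false-negative detection noise per expanded region;
* aligned sequence sets built on a packaged synthetic reference frame
  (an 80-column PSBD-style alignment, not any curated study alignment)
  with discriminating motifs planted or omitted per record, a planted
  catalytic-triad state, and i.i.d. per-site mutations.

Seeds are mandatory in every scenario; identical scenario plus seed
gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import steric
from .occupancy import mapback_count
from .seqdiscrim import AMINO_ACIDS, HYDROPHOBIC, AlignedSeqSet, MotifRule, default_rules
from .symmetry import RotationGroup, generate_point_group, matrix_to_euler

__all__ = [
    "REF_FRAME_LENGTH",
    "TRIAD_COLUMN",
    "reference_frame",
    "OccupancyScenario",
    "CoreSimulation",
    "simulate_cores",
    "emulate_fig1e_table",
    "SeqScenario",
    "simulate_sequences",
]

# --------------------------------------------------------------------------
# synthetic reference alignment frame
# --------------------------------------------------------------------------

REF_FRAME_LENGTH = 80
#: 1-based column of the canonical transacetylase triad His in the frame.
TRIAD_COLUMN = 78

# Background for the synthetic frame: a fixed 20-residue tile (no His, so
# the triad column alone controls catalytic state).
_BACKGROUND = ("MSKLAEVTGDRLPQWFANQE" * 4)[:REF_FRAME_LENGTH]

# 1-based column edits defining the two reference sequences.
_E2_EDITS = {
    19: "E", 20: "K", 21: "G",              # polar helix-1 motif 'EKG'
    37: "R", 38: "G", 39: "T",              # Arg preceding the conserved Gly
    43: "D", 44: "S", 45: "K", 46: "S", 47: "K", 48: "S",
    49: "E", 50: "S", 51: "A",
    TRIAD_COLUMN: "H",                       # catalytically active
}
_E3BP_EDITS = {
    19: "Q", 20: "K", 21: "A",
    37: "T", 38: "G", 39: "R",              # Arg following the conserved Gly
    43: "D", 44: "S", 45: "L", 46: "L", 47: "K", 48: "V",  # Asp + hydrophobic
    49: "G", 50: "A", 51: "I",              # helix-2 termination 'GxI'
    TRIAD_COLUMN: "S",                       # triad His lost
}
_ASC_EXTENSION_EDITS = {68: "L", 69: "S", 70: "V", 71: "T", 72: "I", 73: "A", 74: "L"}


def _apply_edits(seq: str, edits: dict[int, str]) -> str:
    chars = list(seq)
    for col, aa in edits.items():
        chars[col - 1] = aa
    return "".join(chars)


def reference_frame(label: str, group: str = "Pez") -> str:
    """Synthetic reference sequence for an E2 or E3BP record in the frame.

    The frame is a stand-in constructed for testing, not a curated
    alignment: motif columns match the packaged rule set and everything
    else is a fixed neutral background.  Ascomycota E3BP additionally
    carries the alternating-hydrophobic extension at columns 68-74.
    """
    if label == "E2":
        return _apply_edits(_BACKGROUND, _E2_EDITS)
    if label == "E3BP":
        seq = _apply_edits(_BACKGROUND, _E3BP_EDITS)
        if group == "Asc":
            seq = _apply_edits(seq, _ASC_EXTENSION_EDITS)
        return seq
    raise ValueError(f"unknown label {label!r}; accepted: 'E2', 'E3BP'")


# --------------------------------------------------------------------------
# core occupancy simulation
# --------------------------------------------------------------------------

#: Default trimer-count distribution: majority of cores carrying 3-4
#: trimers, matching the observed predominance of high occupancy.
DEFAULT_TRIMER_DIST = {0: 0.05, 1: 0.10, 2: 0.20, 3: 0.35, 4: 0.30}

#: Placeholder detection-noise rates.  The real classification's error
#: rates are unknown; these are labelled as placeholders in reports.
DEFAULT_FP_RATE = 0.01
DEFAULT_FN_RATE = 0.05


@dataclass(frozen=True)
class OccupancyScenario:
    """Ground-truth description of a simulated core population.

    ``trimer_dist`` is either a fixed trimer count or a probability
    distribution over counts; each core's trimers are placed on a
    uniformly chosen site subset compatible under the angular exclusion.
    ``fp_rate`` / ``fn_rate`` are the per-expanded-region probabilities
    of a spurious or missed detection, applied independently.
    """

    n_cores: int
    trimer_dist: dict[int, float] | int = field(
        default_factory=lambda: dict(DEFAULT_TRIMER_DIST)
    )
    fp_rate: float = DEFAULT_FP_RATE
    fn_rate: float = DEFAULT_FN_RATE
    exclusion_deg: float = steric.DEFAULT_EXCLUSION_DEG
    seed: int = 0

    def __post_init__(self):
        if self.n_cores <= 0:
            raise ValueError("n_cores must be positive")
        if not (0.0 <= self.fp_rate <= 1.0 and 0.0 <= self.fn_rate <= 1.0):
            raise ValueError("detection noise rates must lie in [0, 1]")
        if isinstance(self.trimer_dist, dict):
            probs = np.array(list(self.trimer_dist.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("trimer-count distribution must be non-negative and sum to 1")


@dataclass(frozen=True)
class CoreSimulation:
    """Output bundle of :func:`simulate_cores`."""

    particles: pd.DataFrame   # particle_id, core_id, rot, tilt, psi, origin_x/y
    truth: pd.DataFrame       # core_id, k_true, occupied site indices
    flags: pd.DataFrame       # core_id, parent_particle_id, operator_index,
                              # site_index, occupied (one row per expanded region)
    group: RotationGroup
    geometry: steric.CoreGeometry
    scenario: OccupancyScenario


def operator_site_labels(
    group: RotationGroup, geometry: steric.CoreGeometry, site_index: int = 0
) -> np.ndarray:
    """Geometry site index imaged by each group operator.

    Operator g, applied on the map side, centers the expanded
    sub-particle on the physical site ``g @ v0`` where ``v0`` is the
    canonical reference site.  Each of the 20 sites is hit by exactly 3
    operators (the stabilizer cosets of a 3-fold axis).
    """
    v0 = geometry.sites[site_index]
    images = np.einsum("gij,j->gi", group.operators, v0)
    dots = np.clip(images @ geometry.sites.T, -1.0, 1.0)
    labels = np.argmax(dots, axis=1)
    if np.min(np.max(dots, axis=1)) < 1.0 - 1e-9:
        raise RuntimeError("operator image does not coincide with any geometry site")
    return labels


def _draw_trimer_counts(scenario: OccupancyScenario, rng: np.random.Generator, kmax: int) -> np.ndarray:
    if isinstance(scenario.trimer_dist, int):
        k = scenario.trimer_dist
        if k > kmax:
            raise ValueError(
                f"requested {k} trimers exceeds the placement maximum {kmax} at "
                f"{scenario.exclusion_deg} degree exclusion"
            )
        return np.full(scenario.n_cores, k, dtype=int)
    ks = np.array(sorted(scenario.trimer_dist), dtype=int)
    if ks.max() > kmax:
        raise ValueError(
            f"distribution includes {ks.max()} trimers, above the placement "
            f"maximum {kmax} at {scenario.exclusion_deg} degree exclusion"
        )
    probs = np.array([scenario.trimer_dist[int(k)] for k in ks], dtype=float)
    return rng.choice(ks, size=scenario.n_cores, p=probs)


def simulate_cores(scenario: OccupancyScenario) -> CoreSimulation:
    """Simulate cores with planted trimer occupancy and detection noise.

    Orientations are uniform over SO(3); each core's k trimers occupy a
    uniformly chosen pairwise-compatible subset of the 20 interior
    3-fold sites; each of the 60 expanded regions is flagged occupied
    with probability ``1 - fn_rate`` if its central site carries a
    trimer and ``fp_rate`` otherwise.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(scenario.seed)
    group = generate_point_group("I")
    geometry = steric.build_core_geometry()
    placement = steric.max_placement(geometry, scenario.exclusion_deg)
    counts = _draw_trimer_counts(scenario, rng, placement.max_count)

    subsets_by_k = {
        int(k): steric.compatible_subsets(geometry, int(k), scenario.exclusion_deg)
        for k in np.unique(counts)
    }
    site_labels = operator_site_labels(group, geometry)
    n = scenario.n_cores

    quat = rng.normal(size=(n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    rot, tilt, psi = matrix_to_euler(Rotation.from_quat(quat).as_matrix())
    particles = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "core_id": np.arange(n),
            "rot": rot,
            "tilt": tilt,
            "psi": psi,
            "origin_x": rng.uniform(-5.0, 5.0, size=n),
            "origin_y": rng.uniform(-5.0, 5.0, size=n),
        }
    )

    truth_rows = []
    occupied_region = np.zeros((n, group.order), dtype=bool)
    for i in range(n):
        k = int(counts[i])
        options = subsets_by_k[k]
        chosen = options[rng.integers(len(options))] if options else ()
        truth_rows.append({"core_id": i, "k_true": k, "sites": chosen})
        occupied_region[i] = np.isin(site_labels, chosen)

    u = rng.random(size=(n, group.order))
    flagged = np.where(occupied_region, u < 1.0 - scenario.fn_rate, u < scenario.fp_rate)

    flags = pd.DataFrame(
        {
            "core_id": np.repeat(np.arange(n), group.order),
            "parent_particle_id": np.repeat(np.arange(n), group.order),
            "operator_index": np.tile(np.arange(group.order), n),
            "site_index": np.tile(site_labels, n),
            "occupied": flagged.ravel(),
        }
    )
    return CoreSimulation(
        particles=particles,
        truth=pd.DataFrame(truth_rows),
        flags=flags,
        group=group,
        geometry=geometry,
        scenario=scenario,
    )


def emulate_fig1e_table(scenario: OccupancyScenario) -> pd.DataFrame:
    """Per-core detection-count table in the published source-data layout.

    Runs the core simulation and maps occupancy flags back to their
    parent cores, producing a ``core_id, detection_count`` table that is
    a drop-in for the study-style supplementary data file.
    """
    sim = simulate_cores(scenario)
    return mapback_count(sim.flags, known_cores=sim.particles["core_id"])


# --------------------------------------------------------------------------
# sequence simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqScenario:
    """Ground-truth description of a simulated aligned sequence set.

    ``n_per_group`` maps taxon-group labels to record counts and
    ``label_per_group`` assigns each group an E2 or E3BP identity
    (default: all E3BP).  ``plant`` overrides individual motif rules by
    name (True = force-plant the motif, False = scrub it); the triad
    state defaults to the identity-implied one (E2 active, E3BP
    inactive).  Mutations hit each column independently and always
    change the residue.
    """

    n_per_group: dict[str, int]
    label_per_group: dict[str, str] = field(default_factory=dict)
    plant: dict[str, bool] = field(default_factory=dict)
    mutation_prob: float = 0.0
    triad_state: str | None = None   # "active" | "inactive" | None (implied)
    seed: int = 0

    def __post_init__(self):
        if not self.n_per_group or any(v <= 0 for v in self.n_per_group.values()):
            raise ValueError("n_per_group must request at least one record per group")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation probability must lie in [0, 1]")
        if self.triad_state not in (None, "active", "inactive"):
            raise ValueError("triad_state must be 'active', 'inactive' or None")


def _concrete_pattern(rule: MotifRule) -> str:
    """Instantiate the rule's first pattern into concrete residues."""
    lo = rule.span[0]
    out = []
    for offset, p in enumerate(rule.patterns[0]):
        if p == "x":
            out.append(_BACKGROUND[lo - 1 + offset])
        elif p == "h":
            out.append("L")
        else:
            out.append(p)
    return "".join(out)


def _scrubbed_pattern(rule: MotifRule) -> str:
    """Non-matching filler for a rule span (background, de-hydrophobized)."""
    lo, hi = rule.span
    filler = list(_BACKGROUND[lo - 1 : hi])
    for idx, p in enumerate(rule.patterns[0]):
        if p != "x" and (filler[idx] == p or (p == "h" and filler[idx] in HYDROPHOBIC)):
            filler[idx] = "S"  # serine matches neither exact nor hydrophobic slots
    return "".join(filler)


def simulate_sequences(scenario: SeqScenario) -> tuple[AlignedSeqSet, pd.DataFrame]:
    """Generate an aligned sequence set with planted motifs and triad states.

    Records are built from the synthetic reference frame for their
    group's identity, motif rules are planted or scrubbed as requested,
    the triad column is set, and i.i.d. substitutions are applied at the
    scenario's mutation probability.  Returns the alignment plus a
    ground-truth table (seq_id, group, label, triad state).
    """
    rules = {r.name: r for r in default_rules()}
    for name in scenario.plant:
        if name not in rules:
            raise ValueError(f"unknown motif name {name!r}; known: {sorted(rules)}")
    rng = np.random.default_rng(scenario.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    ids, groups, seqs, truth_rows = [], [], [], []
    for group in sorted(scenario.n_per_group):
        label = scenario.label_per_group.get(group, "E3BP")
        base = reference_frame(label, group=group)
        for rule_name, want in scenario.plant.items():
            rule = rules[rule_name]
            lo, hi = rule.span
            block = _concrete_pattern(rule) if want else _scrubbed_pattern(rule)
            base = base[: lo - 1] + block + base[hi:]
        triad = scenario.triad_state or ("active" if label == "E2" else "inactive")
        base = _apply_edits(base, {TRIAD_COLUMN: "H" if triad == "active" else "S"})

        for i in range(scenario.n_per_group[group]):
            chars = np.array(list(base))
            hit = rng.random(len(chars)) < scenario.mutation_prob
            for j in np.flatnonzero(hit):
                alternatives = aa[aa != chars[j]]
                chars[j] = alternatives[rng.integers(len(alternatives))]
            sid = f"{group}|synth_{label}_{i:03d}"
            ids.append(sid)
            groups.append(group)
            seqs.append("".join(chars))
            truth_rows.append(
                {"seq_id": sid, "group": group, "label": label, "triad_state": triad}
            )
    msa = AlignedSeqSet(ids=tuple(ids), groups=tuple(groups), seqs=tuple(seqs))
    return msa, pd.DataFrame(truth_rows)
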