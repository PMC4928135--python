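"""Synthetic cohorts of voxel-level tract counts with known ground truth.

No public clinical tractography dataset accompanies the method, so the
package validates itself on simulated cohorts.  The generator uses a
Dirichlet-multinomial hierarchy, the minimal model matching the data type
(compositional connection-probability profiles plus count sampling):

* per node, a population connection profile is drawn from a Dirichlet over
  the m-1 possible targets (baseline concentration controls sparsity);
* per subject, a subject profile is drawn from
  Dirichlet(subject_dispersion x population profile) -- the dispersion
  scalar sets between-subject variability (larger = more homogeneous);
* planted effects multiply the concentration of chosen (seed, target)
  entries for subjects of the affected group before the subject draw, so a
  factor > 1 plants hyper-connectivity and a factor < 1 hypo-connectivity,
  in *relative* probability, exactly the quantity the fingerprint measures;
* per seed voxel, counts are drawn from
  Multinomial(samples_per_voxel, subject profile).

Everything is deterministic under the spec's seed.  ``write_fixture``
serializes a cohort in the exact on-disk layout the readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fingerprint import RegionAtlas, VoxelCounts, build_fingerprint_matrix
from .grouptest import GroupDesign
from .similarity import CohortFingerprints


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative concentration change on one directed edge in one group."""

    seed_node: int
    target: int
    factor: float
    group: str

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("effect factor must be positive")
        if self.seed_node == self.target:
            raise ValueError("cannot plant an effect on a self-connection")


@dataclass(frozen=True)
class SimCohortSpec:
    """Generative parameters for a synthetic multi-group cohort.

    Defaults are the package's reference study conditions: 20 regions of
    20 voxels, 5000 tract samples per voxel (the standard probtrackx
    setting), baseline Dirichlet concentration 0.5 (sparse, hub-dominated
    profiles as seen in real tractography) and subject dispersion 150
    (moderate between-subject variability of compositional profiles).
    """

    m: int = 20
    voxels_per_region: int | tuple[int, ...] = 20
    samples_per_voxel: int = 5000
    n_per_group: tuple[int, ...] = (16, 17)
    group_names: tuple[str, ...] = ()
    baseline_concentration: float | tuple[float, ...] = 0.5
    subject_dispersion: float = 150.0
    effects: tuple[PlantedEffect, ...] = ()
    distance_attenuation: np.ndarray | None = None  # optional (m, m), shared
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least 2 regions")
        base = np.atleast_1d(np.asarray(self.baseline_concentration, dtype=float))
        if base.size not in (1, self.m):
            raise ValueError(
                "baseline_concentration must be a scalar or a length-m vector"
            )
        if np.any(base <= 0) or self.subject_dispersion <= 0:
            raise ValueError("concentrations must be positive")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs at least 2 subjects")
        if not self.group_names:
            names = tuple(f"group{g + 1}" for g in range(len(self.n_per_group)))
            object.__setattr__(self, "group_names", names)
        if len(self.group_names) != len(self.n_per_group):
            raise ValueError("group_names must match n_per_group")
        for e in self.effects:
            if not (0 <= e.seed_node < self.m and 0 <= e.target < self.m):
                raise ValueError(f"effect references invalid region: {e}")
            if e.group not in self.group_names:
                raise ValueError(f"effect group {e.group!r} not in {self.group_names}")

    @property
    def voxel_counts_per_region(self) -> tuple[int, ...]:
        v = self.voxels_per_region
        return tuple(v for _ in range(self.m)) if isinstance(v, int) else tuple(v)

    def default_atlas(self) -> RegionAtlas:
        half = self.m // 2
        return RegionAtlas(
            labels=tuple(f"R{i:03d}" for i in range(self.m)),
            hemispheres=tuple("l" if i < half else "r" for i in range(self.m)),
        )


@dataclass(frozen=True)
class SimulatedCohort:
    """Generated cohort plus its ground truth."""

    spec: SimCohortSpec
    atlas: RegionAtlas
    subjects: tuple[str, ...]
    design: GroupDesign
    voxel_counts: tuple[tuple[VoxelCounts, ...], ...]  # [subject][region]
    subject_profiles: np.ndarray  # (n_subjects, m, m) ground-truth profiles
    effects: tuple[PlantedEffect, ...]

    def fingerprints(self) -> CohortFingerprints:
        fms = [
            build_fingerprint_matrix(list(per_subject), self.atlas, subject=sid)
            for sid, per_subject in zip(self.subjects, self.voxel_counts)
        ]
        return CohortFingerprints.from_matrices(fms, self.design.labels)


def _embed(vec: np.ndarray, m: int, seed_node: int) -> np.ndarray:
    """Place an (m-1)-vector over non-self targets into an m-vector."""
    out = np.zeros(m)
    out[np.arange(m) != seed_node] = vec
    return out


def generate_cohort(spec: SimCohortSpec, rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Draw a full cohort of voxel-level tract counts from the spec."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    m = spec.m
    groups: list[str] = []
    for name, n_g in zip(spec.group_names, spec.n_per_group):
        groups.extend([name] * n_g)
    n = len(groups)
    subjects = tuple(f"sub{s:03d}" for s in range(n))
    voxels = spec.voxel_counts_per_region

    # population profile per node, over the m-1 non-self targets; a vector
    # baseline concentration (per-target) shapes the expected profile
    base = np.atleast_1d(np.asarray(spec.baseline_concentration, dtype=float))
    base = np.broadcast_to(base, (m,)) if base.size > 1 else np.full(m, base[0])
    pop = np.zeros((m, m))
    for k in range(m):
        mask = np.arange(m) != k
        pop[k] = _embed(rng.dirichlet(base[mask]), m, k)
    if spec.distance_attenuation is not None:
        att = np.asarray(spec.distance_attenuation, dtype=float)
        if att.shape != (m, m) or np.any(att <= 0):
            raise ValueError("distance_attenuation must be a positive (m, m) array")
        pop = pop * att
        pop /= pop.sum(axis=1, keepdims=True)

    effects_by_group: dict[str, list[PlantedEffect]] = {}
    for e in spec.effects:
        effects_by_group.setdefault(e.group, []).append(e)

    profiles = np.zeros((n, m, m))
    all_counts: list[tuple[VoxelCounts, ...]] = []
    for s, grp in enumerate(groups):
        conc = spec.subject_dispersion * pop
        for e in effects_by_group.get(grp, ()):
            conc = conc.copy()
            conc[e.seed_node, e.target] *= e.factor
        per_subject: list[VoxelCounts] = []
        for k in range(m):
            mask = np.arange(m) != k
            prof = _embed(rng.dirichlet(conc[k, mask]), m, k)
            profiles[s, k] = prof
            counts = np.zeros((voxels[k], m), dtype=np.int64)
            counts[:, mask] = rng.multinomial(
                spec.samples_per_voxel, prof[mask], size=voxels[k]
            )
            per_subject.append(
                VoxelCounts(seed=k, counts=counts,
                            samples_per_voxel=spec.samples_per_voxel)
            )
        all_counts.append(tuple(per_subject))

    return SimulatedCohort(
        spec=spec,
        atlas=spec.default_atlas(),
        subjects=subjects,
        design=GroupDesign(labels=tuple(groups)),
        voxel_counts=tuple(all_counts),
        subject_profiles=profiles,
        effects=spec.effects,
    )


def write_fixture(cohort: SimulatedCohort, out_dir: str | Path, force: bool = False) -> Path:
    """Write a cohort as the on-disk fixture layout; returns the manifest path.

    Layout: ``atlas.tsv``, ``design.tsv``, ``counts/<subject>/<region>.tsv``
    (one voxel x target integer matrix per seed region per subject) and a
    ``manifest.tsv`` mapping subject, region to the count file.
    """
    from . import io  # deferred: io imports simulate types for reading

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    io.write_atlas(cohort.atlas, out / "atlas.tsv")
    io.write_design(cohort.subjects, cohort.design, out / "design.tsv")
    rows = []
    for sid, per_subject in zip(cohort.subjects, cohort.voxel_counts):
        sub_dir = out / "counts" / sid
        sub_dir.mkdir(parents=True, exist_ok=True)
        for vc in per_subject:
            label = cohort.atlas.labels[vc.seed]
            rel = Path("counts") / sid / f"{label}.tsv"
            np.savetxt(out / rel, vc.counts, fmt="%d", delimiter="\t")
            rows.append((sid, label, str(rel)))
    manifest = out / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("subject\tregion\tpath\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return manifest
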