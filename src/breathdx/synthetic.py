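"""Synthetic eNose and IMS cohorts with planted, tunable class structure.

No raw instrument data accompany the study design this package implements,
so every downstream stage is exercised on generated cohorts that reproduce
the *statistical* structure the analysis assumes:

* eNose: three diagnostic groups (AD, PD, HC) across up to two sites,
  triplicate 32-channel sensor readings; group effects are additive
  per-sensor mean shifts, site batch effects are additive per-sensor
  offsets, and measurement noise is independent Gaussian per channel.
* IMS: per-subject peak intensities for the analytes of a given threshold
  cascade, planted so that at ``overlap = 0`` the cascade classifies every
  sample correctly, with extra uninformative analytes so tree induction has
  to find the signal.

Overlap semantics
-----------------
``overlap`` is the expected misclassification fraction of the generating
tree.  A sample is a "decoy" with probability q = min(1, overlap * g/(g-1))
for g classes; a decoy's intensities are drawn from a uniformly random
class (possibly its own), so a decoy is misclassified with probability
(g-1)/g and the overall expected misclassification fraction equals
``overlap`` whenever overlap <= (g-1)/g.  Beyond that it saturates at
chance level: with overlap = 1 the intensities are label-independent, so
accuracy approaches the chance rate (0.5 for two equiprobable classes).

A single integer seed fully determines every cohort; replicate noise is
drawn sequentially so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ims import Analyte, DecisionTree, PeakTable
from .metrics import ValidationError
from .preprocess import GROUPS, SampleRecord

#: Planted intensity-band geometry, as fractions of each node threshold t.
#: An *expressed* signature compound sits in a low band at 0.5 t; an
#: unexpressed compound sits above the cut, at 1.4 t for affected subjects
#: (the disease process partially depresses the whole signature) and at the
#: healthy background level 2.0 t otherwise.  With band sd t/12 every band
#: is > 4 sd clear of the cut and of its neighbours, so at overlap 0 the
#: classes are separable and tree induction is exactly recoverable.
_BAND_SD_FRAC = 1 / 12
_LOW_FRAC = 0.5
_AFFECTED_FRAC = 1.4
_HEALTHY_FRAC = 2.0


@dataclass
class CohortSpec:
    """Cohort layout: per-site group sizes, sensor count, replicates, seed."""

    site_groups: dict[str, dict[str, int]]
    n_sensors: int = 32
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.site_groups:
            raise ValidationError("at least one site required")
        for site, groups in self.site_groups.items():
            if not groups:
                raise ValidationError(f"site {site!r} has no groups")
            for g, n in groups.items():
                if g not in GROUPS:
                    raise ValidationError(f"unknown group label {g!r}")
                if n < 1:
                    raise ValidationError(f"group size must be >= 1 ({site}/{g})")
        if self.n_sensors < 1 or self.n_replicates < 1:
            raise ValidationError("n_sensors and n_replicates must be >= 1")

    @classmethod
    def single_site(cls, groups: dict[str, int], site: str = "Marburg",
                    **kw) -> "CohortSpec":
        return cls(site_groups={site: dict(groups)}, **kw)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for gs in self.site_groups.values():
            for g in gs:
                seen.setdefault(g)
        return list(seen)

    @property
    def total_samples(self) -> int:
        return sum(n for gs in self.site_groups.values() for n in gs.values())


@dataclass
class EffectModel:
    """Planted effect sizes for the eNose generator.

    ``sensor_shift`` maps group label -> length-``n_sensors`` additive mean
    offset; ``site_offset`` maps site label -> additive batch offset;
    ``sensor_noise_sd`` is the per-channel Gaussian noise sd (response
    units); ``baseline`` the common mean response.
    """

    sensor_shift: dict[str, np.ndarray] = field(default_factory=dict)
    sensor_noise_sd: float = 1.0
    site_offset: dict[str, np.ndarray] = field(default_factory=dict)
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.sensor_noise_sd <= 0:
            raise ValidationError("sensor noise sd must be positive")
        self.sensor_shift = {k: np.asarray(v, dtype=float)
                             for k, v in self.sensor_shift.items()}
        self.site_offset = {k: np.asarray(v, dtype=float)
                            for k, v in self.site_offset.items()}

    @classmethod
    def planted_sensor(cls, n_sensors: int, group: str, sensor: int,
                       shift: float = 4.0, noise_sd: float = 1.0,
                       **kw) -> "EffectModel":
        """Effect confined to one sensor for one group (1-based index)."""
        v = np.zeros(n_sensors)
        v[sensor - 1] = shift
        return cls(sensor_shift={group: v}, sensor_noise_sd=noise_sd, **kw)


def generate_enose_cohort(spec: CohortSpec,
                          effect: EffectModel) -> list[SampleRecord]:
    """Triplicate sensor panels with planted group and site effects.

    Deterministic in ``spec.seed``; iterates sites and groups in their given
    order and draws replicate noise sequentially.
    """
    p = spec.n_sensors
    for name, vecs in (("sensor_shift", effect.sensor_shift),
                       ("site_offset", effect.site_offset)):
        for k, v in vecs.items():
            if v.shape != (p,):
                raise ValidationError(
                    f"{name}[{k!r}] has length {v.shape}, expected ({p},)")
    rng = np.random.default_rng(spec.seed)
    records: list[SampleRecord] = []
    counter = 0
    for site, groups in spec.site_groups.items():
        off = effect.site_offset.get(site, np.zeros(p))
        for group, n in groups.items():
            shift = effect.sensor_shift.get(group, np.zeros(p))
            mean = effect.baseline + shift + off
            for _ in range(n):
                counter += 1
                reps = [mean + rng.normal(0.0, effect.sensor_noise_sd, size=p)
                        for _ in range(spec.n_replicates)]
                records.append(SampleRecord(
                    subject_id=f"{site}-{group}-{counter:03d}",
                    group=group, site=site, replicates=reps))
    return records


# ---------------------------------------------------------------------------
# IMS cohorts planted from a threshold cascade
# ---------------------------------------------------------------------------

def _leaf_constraints(tree: DecisionTree) -> dict[str, list[list[tuple]]]:
    """Per class: list of leaves, each a list of (node, fires?) constraints."""
    leaves: dict[str, list[list[tuple]]] = {c: [] for c in tree.classes}
    prefix: list[tuple] = []
    for node in tree.nodes:
        leaves[node.class_if_true].append(prefix + [(node, True)])
        prefix = prefix + [(node, False)]
    leaves[tree.else_class].append(prefix)
    return leaves


def _draw_side(rng: np.random.Generator, node, fires: bool,
               high_frac: float) -> float:
    """Intensity strictly on the requested side of a node's threshold."""
    t = node.threshold
    sd = _BAND_SD_FRAC * t if t > 0 else 0.01
    op_low = node.op in ("<", "<=")
    low_side = fires if op_low else not fires
    if low_side:
        v = rng.normal(_LOW_FRAC * t, sd)
        hi = np.nextafter(t, -np.inf) if node.op in ("<", ">=") else t
        return float(np.clip(v, 0.0, hi))
    v = rng.normal(high_frac * t, sd)
    lo = t if node.op in ("<", ">=") else np.nextafter(t, np.inf)
    return float(max(v, lo))


def generate_ims_cohort(
    spec: CohortSpec,
    tree: DecisionTree,
    overlap: float = 0.0,
    n_noise_analytes: int = 4,
) -> PeakTable:
    """Peak table whose class structure is planted from a threshold cascade.

    Every clean sample routes through ``tree`` to a leaf of its true class
    (classes with several leaves have one chosen at random); analytes beyond
    the sample's routing path, and ``n_noise_analytes`` extra uninformative
    peaks, are drawn from both sides of their cuts at random.  See the
    module docstring for the decoy/overlap model.
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValidationError("overlap must lie in [0, 1]")
    classes = spec.groups
    missing = [c for c in classes if c not in tree.classes]
    if missing:
        raise ValidationError(f"tree has no leaf for groups {missing}")
    g = len(classes)
    q = min(1.0, overlap * g / (g - 1)) if g > 1 else 0.0
    rng = np.random.default_rng(spec.seed)
    leaves = _leaf_constraints(tree)

    def draw_sample(target: str) -> dict[str, float]:
        # Unexpressed compounds of affected subjects sit in the partially
        # depressed band; the else (healthy) class at the full background.
        high_frac = _HEALTHY_FRAC if target == tree.else_class else _AFFECTED_FRAC
        paths = leaves[target]
        path = paths[rng.integers(len(paths))]
        values: dict[str, float] = {}
        for node, fires in path:
            values[node.analyte] = _draw_side(rng, node, fires, high_frac)
        # Analytes past the sample's exit leaf follow the continuation side.
        for node in tree.nodes:
            if node.analyte not in values:
                values[node.analyte] = _draw_side(rng, node, False, high_frac)
        return values

    analytes = [Analyte(peak_id=n.analyte, drift_time=0.5 + 0.05 * i,
                        retention_time=10.0 * (i + 1))
                for i, n in enumerate(tree.nodes)]
    noise_ids = [f"N{i + 1:02d}" for i in range(n_noise_analytes)]
    analytes += [Analyte(peak_id=pid, drift_time=0.8 + 0.05 * i,
                         retention_time=100.0 + 10.0 * i)
                 for i, pid in enumerate(noise_ids)]

    rows, labels, sample_ids = [], [], []
    counter = 0
    for site, groups in spec.site_groups.items():
        for group, n in groups.items():
            for _ in range(n):
                counter += 1
                decoy = rng.random() < q
                target = classes[rng.integers(g)] if decoy else group
                vals = draw_sample(target)
                noise = rng.uniform(0.0, 0.05, size=n_noise_analytes)
                row = [vals[a.peak_id] for a in analytes[: len(tree.nodes)]]
                rows.append(np.concatenate([row, noise]))
                labels.append(group)
                sample_ids.append(f"{site}-{group}-{counter:03d}")
    return PeakTable(analytes=analytes, intensities=np.array(rows),
                     labels=labels, sample_ids=sample_ids)
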