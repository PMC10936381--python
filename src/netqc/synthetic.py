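"""Seeded generators for synthetic cell maps and two-core feature tables.

These generators provide the statistical structure each analysis stage
assumes — complete spatial randomness, Thomas-style clustering, attraction,
hard-core inhibition, and region-restricted (multi-compartment) occupancy —
so the whole toolkit is testable without any imaging data. Every generator is
a pure function of its arguments including the seed.

The canned scenarios used by the validation suite (CSR calibration,
attraction, repulsion, structured-tissue asymmetry, two-core staining shift)
pin all their parameters in module constants below, so quantitative
expectations stay meaningful across versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GenerationError, ValidationError
from .io_tables import CellTable, FeatureTable

_REJECTION_CAP = 200  # resampling rounds before giving up


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] x [y0, y1]."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValidationError(f"degenerate rectangle: {self}")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= self.x0) & (xy[:, 0] <= self.x1)
            & (xy[:, 1] >= self.y0) & (xy[:, 1] <= self.y1)
        )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.column_stack(
            [rng.uniform(self.x0, self.x1, n), rng.uniform(self.y0, self.y1, n)]
        )

    def within(self, outer: "Rect") -> bool:
        return (
            self.x0 >= outer.x0 and self.y0 >= outer.y0
            and self.x1 <= outer.x1 and self.y1 <= outer.y1
        )


# --- placement rules --------------------------------------------------------


@dataclass(frozen=True)
class Uniform:
    """Homogeneous (binomial) placement; ``region`` restricts the support."""

    region: Rect | None = None


@dataclass(frozen=True)
class Clustered:
    """Thomas-style clusters: uniform parents, isotropic-normal offspring.

    Each of the class's cells is attached to a uniformly chosen parent, so
    exact per-class counts are honored; offspring falling outside the support
    are resampled (keeping isotropy near edges rather than reflecting).
    """

    n_parents: int
    dispersion_sd: float
    region: Rect | None = None


@dataclass(frozen=True)
class AttractedTo:
    """Each cell is a normal displacement from a uniformly chosen cell of ``label``."""

    label: str
    displacement_sd: float
    region: Rect | None = None


@dataclass(frozen=True)
class InhibitedFrom:
    """Uniform placement rejected inside the exclusion radius of every ``label`` cell."""

    label: str
    exclusion_radius: float
    region: Rect | None = None


Placement = Uniform | Clustered | AttractedTo | InhibitedFrom


@dataclass(frozen=True)
class ClassSpec:
    label: str
    n_cells: int
    placement: Placement


@dataclass(frozen=True)
class TissueScenario:
    """A reproducible recipe for one synthetic tissue sample.

    Classes are generated in order; a placement may reference only labels
    generated before it. The same label may appear in several entries, which
    composes mixtures (e.g. a class that is mostly compartment-bound with a
    sprinkling over the whole window).
    """

    window: tuple[float, float]
    classes: list[ClassSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ValidationError("window sides must be positive")
        outer = Rect(0.0, 0.0, float(w), float(h))
        seen: set[str] = set()
        for spec in self.classes:
            if spec.n_cells < 1:
                raise ValidationError(f"class {spec.label!r} needs n_cells >= 1")
            p = spec.placement
            if isinstance(p, (AttractedTo, InhibitedFrom)) and p.label not in seen:
                raise ValidationError(
                    f"placement of {spec.label!r} references {p.label!r}, "
                    "which is not defined earlier"
                )
            if p.region is not None and not p.region.within(outer):
                raise ValidationError(f"region of {spec.label!r} lies outside the window")
            seen.add(spec.label)


def _support(scenario: TissueScenario, placement: Placement) -> Rect:
    w, h = scenario.window
    return placement.region or Rect(0.0, 0.0, float(w), float(h))


def _resample_into(
    rng: np.random.Generator, draw, support: Rect, n: int, what: str
) -> np.ndarray:
    """Call ``draw(m)`` until n points fall inside ``support`` (isotropy-preserving clip)."""
    points = np.empty((0, 2))
    for _ in range(_REJECTION_CAP):
        need = n - len(points)
        if need == 0:
            return points
        cand = draw(need)
        points = np.vstack([points, cand[support.contains(cand)]])
    raise GenerationError(
        f"could not place {what}: resampling cap hit; enlarge the window or "
        "relax the placement constraints"
    )


def generate_tissue(scenario: TissueScenario) -> CellTable:
    """Realize a :class:`TissueScenario` into a validated :class:`CellTable`."""
    rng = np.random.default_rng(scenario.seed)
    all_xy: list[np.ndarray] = []
    all_labels: list[str] = []
    by_label: dict[str, list[np.ndarray]] = {}

    for spec in scenario.classes:
        support = _support(scenario, spec.placement)
        p = spec.placement
        if isinstance(p, Uniform):
            xy = support.sample(rng, spec.n_cells)
        elif isinstance(p, Clustered):
            parents = support.sample(rng, p.n_parents)
            assignment = rng.integers(0, p.n_parents, spec.n_cells)

            def draw(m, parents=parents, assignment=assignment, p=p, rng=rng):
                # keep each offspring bound to its parent; resample displacement only
                idx = rng.integers(0, len(parents), m) if m != len(assignment) else assignment
                return parents[idx] + rng.normal(0.0, p.dispersion_sd, (m, 2))

            # first pass uses the fixed assignment; shortfalls redraw parent+offset
            xy = _resample_into(rng, draw, support, spec.n_cells, f"clustered {spec.label!r}")
        elif isinstance(p, AttractedTo):
            anchors = np.vstack(by_label[p.label])

            def draw(m, anchors=anchors, p=p, rng=rng):
                idx = rng.integers(0, len(anchors), m)
                return anchors[idx] + rng.normal(0.0, p.displacement_sd, (m, 2))

            xy = _resample_into(rng, draw, support, spec.n_cells, f"attracted {spec.label!r}")
        elif isinstance(p, InhibitedFrom):
            anchors = np.vstack(by_label[p.label])
            tree = cKDTree(anchors)

            def draw(m, tree=tree, p=p, support=support, rng=rng):
                cand = support.sample(rng, m)
                dist, _ = tree.query(cand, k=1)
                return cand[dist >= p.exclusion_radius]

            xy = _resample_into(rng, draw, support, spec.n_cells, f"inhibited {spec.label!r}")
        else:  # pragma: no cover - exhaustive over Placement
            raise ValidationError(f"unknown placement: {p!r}")

        all_xy.append(xy)
        all_labels.extend([spec.label] * spec.n_cells)
        by_label.setdefault(spec.label, []).append(xy)

    xy = np.vstack(all_xy)
    ids = np.asarray([f"c{i:06d}" for i in range(len(xy))], dtype=object)
    return CellTable(ids=ids, xy=xy, labels=np.asarray(all_labels, dtype=object))


# --- canned scenarios (parameters pinned here) ------------------------------

WINDOW = (1000.0, 1000.0)

CSR_N_CLASSES = 3
CSR_N_PER_CLASS = 200
CSR_RADIUS = 50.0

ATTRACTION_RADIUS = 50.0
ATTRACTION_N = 150
ATTRACTION_DISPLACEMENT_SD = ATTRACTION_RADIUS / 5.0  # B hugs A at d/5

REPULSION_RADIUS = 25.0
REPULSION_N_A = 100
REPULSION_N_B = 150
REPULSION_N_C = 150
REPULSION_EXCLUSION = 2.0 * REPULSION_RADIUS

# Structured two-compartment tissue: Glioma occupies mainly the right half
# (with a 20% whole-window component), "Other" cells colocalize tightly with
# Glioma (normal displacement, sd 5 — an order of magnitude below the test
# radius so the two types see the same local neighborhoods), and TAMM forms
# tight clusters confined to the left half. Non-TAMM cells therefore share
# Glioma's spatial distribution: randomizing Glioma over non-TAMM positions
# reproduces its true layout (score[TAMM][Glioma] ~ 0), while TAMM sits where
# Glioma density is low (score[Glioma][TAMM] strongly negative).
# Composition note: because the Other cells are anchored on Glioma positions,
# the randomization pool's neighborhood profile tracks Glioma's own, and the
# residual cross-seed spread of score[TAMM][Glioma] is ~sqrt(n_Glioma / pool)
# (multinomial anchor noise over the studentizing sd). Keeping Glioma a small
# fraction of the non-TAMM pool makes "Glioma is randomly placed relative to
# TAMM" legible as a tightly near-zero score. See docs/methods.md.
ASYMMETRY_RADIUS = 50.0
ASYMMETRY_GLIOMA_FULL = 40
ASYMMETRY_GLIOMA_RIGHT = 60
ASYMMETRY_OTHER_N = 700
ASYMMETRY_OTHER_SD = 5.0
ASYMMETRY_TAMM_N = 120
ASYMMETRY_TAMM_PARENTS = 4
ASYMMETRY_TAMM_SD = 25.0


def generate_csr_scenario(
    seed: int,
    n_classes: int = CSR_N_CLASSES,
    n_per_class: int = CSR_N_PER_CLASS,
    window: tuple[float, float] = WINDOW,
) -> CellTable:
    """Complete spatial randomness: every class uniform on the window."""
    labels = [f"type{i + 1}" for i in range(n_classes)]
    scenario = TissueScenario(
        window=window,
        classes=[ClassSpec(l, n_per_class, Uniform()) for l in labels],
        seed=seed,
    )
    return generate_tissue(scenario)


def generate_attraction_scenario(seed: int) -> CellTable:
    """B colocalizes with A (displacement sd = d/5); C is an uninvolved uniform class."""
    scenario = TissueScenario(
        window=WINDOW,
        classes=[
            ClassSpec("A", ATTRACTION_N, Uniform()),
            ClassSpec("B", ATTRACTION_N, AttractedTo("A", ATTRACTION_DISPLACEMENT_SD)),
            ClassSpec("C", ATTRACTION_N, Uniform()),
        ],
        seed=seed,
    )
    return generate_tissue(scenario)


def generate_repulsion_scenario(seed: int) -> CellTable:
    """B is excluded from a 2d hard-core zone around every A; C is uniform."""
    scenario = TissueScenario(
        window=WINDOW,
        classes=[
            ClassSpec("A", REPULSION_N_A, Uniform()),
            ClassSpec("B", REPULSION_N_B, InhibitedFrom("A", REPULSION_EXCLUSION)),
            ClassSpec("C", REPULSION_N_C, Uniform()),
        ],
        seed=seed,
    )
    return generate_tissue(scenario)


def generate_asymmetry_scenario(seed: int) -> CellTable:
    """Structured two-compartment tissue reproducing the directional NET pattern.

    Under the conditional null at d = :data:`ASYMMETRY_RADIUS`, the expected
    signature is score[Glioma][TAMM] strongly negative (TAMM clusters live in
    the Glioma-poor compartment) with score[TAMM][Glioma] near zero (Glioma is
    distributed like the rest of the non-TAMM tissue); the full-shuffle null
    is symmetric by construction and cannot show the difference.
    """
    w, h = WINDOW
    left = Rect(0.0, 0.0, w / 2.0, h)
    right = Rect(w / 2.0, 0.0, w, h)
    scenario = TissueScenario(
        window=WINDOW,
        classes=[
            ClassSpec("Glioma", ASYMMETRY_GLIOMA_FULL, Uniform()),
            ClassSpec("Glioma", ASYMMETRY_GLIOMA_RIGHT, Uniform(region=right)),
            ClassSpec("Other", ASYMMETRY_OTHER_N, AttractedTo("Glioma", ASYMMETRY_OTHER_SD)),
            ClassSpec(
                "TAMM",
                ASYMMETRY_TAMM_N,
                Clustered(ASYMMETRY_TAMM_PARENTS, ASYMMETRY_TAMM_SD, region=left),
            ),
        ],
        seed=seed,
    )
    table = generate_tissue(scenario)
    # present classes in the conventional order
    order = {"Glioma": 0, "TAMM": 1, "Other": 2}
    idx = np.argsort([order[l] for l in table.labels], kind="stable")
    return CellTable(ids=table.ids[idx], xy=table.xy[idx], labels=table.labels[idx])


# --- two-core feature tables ------------------------------------------------

TWO_CORE_N_CELLS = 1000
TWO_CORE_N_FEATURES = 4
TWO_CORE_SHIFT = (2.0, 100.0)
TWO_CORE_NOISE_SD = 0.05
# Per-feature bimodal intensity model: a marker-negative background population
# around 1.0 and a marker-positive population around 3.0, with the positive
# fraction varying across features.
_MIX_NEG = (1.0, 0.25)
_MIX_POS = (3.0, 0.5)


def _positive_fraction(k: int, n_features: int) -> float:
    if n_features == 1:
        return 0.4
    return 0.25 + 0.5 * k / (n_features - 1)


def generate_two_core_features(
    n_cells: int = TWO_CORE_N_CELLS,
    n_features: int = TWO_CORE_N_FEATURES,
    shift: tuple[float, float] = TWO_CORE_SHIFT,
    noise_sd: float = TWO_CORE_NOISE_SD,
    seed: int = 0,
) -> FeatureTable:
    """Two cores drawn from the same bimodal intensity model, the second
    distorted by the affine map v -> a*v + b plus independent noise.

    ``a`` must be positive. With shift (1, 0) and zero noise the two cores are
    exchangeable draws from the same distribution.
    """
    a, b = shift
    if a <= 0:
        raise ValidationError("affine slope a must be positive")
    rng = np.random.default_rng(seed)

    def _core(distort: bool) -> np.ndarray:
        out = np.empty((n_cells, n_features))
        for k in range(n_features):
            frac = _positive_fraction(k, n_features)
            pos = rng.random(n_cells) < frac
            vals = np.where(
                pos,
                rng.normal(*_MIX_POS, n_cells),
                rng.normal(*_MIX_NEG, n_cells),
            )
            if distort:
                vals = a * vals + b + rng.normal(0.0, noise_sd, n_cells) if noise_sd > 0 else a * vals + b
            out[:, k] = vals
        return out

    core1 = _core(distort=False)
    core2 = _core(distort=True)
    feature_names = [f"intensity_{k + 1}" for k in range(n_features)]
    data = pd.DataFrame(np.vstack([core1, core2]), columns=feature_names)
    data.insert(0, "sample", ["core1"] * n_cells + ["core2"] * n_cells)
    data.insert(0, "id", [f"c{i:06d}" for i in range(2 * n_cells)])
    return FeatureTable(data=data, feature_names=feature_names)
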