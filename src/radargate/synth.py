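"""Seeded synthetic cytometry cases for APL screening studies.

Three case groups are simulated, mirroring the immunophenotype table of the
screening study:

* hypergranular APL — CD117+/CD33 bright/CD13+/cyMPO+, CD34- and HLA-DR-
  always, high side scatter;
* microgranular APL — additionally CD34+, CD123+ and CD2+ always, medium
  side scatter;
* non-APL AML (NPM1-mutated mimic) — CD117+/CD33 bright/CD34- with variable
  HLA-DR, monocytic markers and CD123, medium-low side scatter.

Each case draws its marker statuses once (shared across tubes, so a CD34-
case is CD34- in every tube that stains CD34), draws a blast percentage
from the study's bone-marrow blast ranges, and emits the blasts plus
lymphocyte / monocyte / granulocyte background populations at canonical
CD45/SSC positions.  Fluorescence intensities are log-normal per marker
status.  Markers whose group rate in the phenotype table is 0% or 100% are
hard constraints and express uniformly at their characteristic level;
markers with intermediate rates behave like aberrant (LAIP-type) antigens —
when a case is positive, a per-case fraction of blasts (uniform on
0.25–0.65) expresses the antigen dimly, the way partial dim aberrancies
present in real AML.  A per-case log-normal intensity factor adds
case-to-case biological variation.

Everything is driven by a single integer seed; identical seeds give
bit-identical cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .events import EventMatrix
from .io_fcs import write_fcs_file
from .panel import PanelConfig, default_panel, normalize_marker

ACQUISITION_EVENTS = 100_000

# log-normal intensity levels (median raw units, sigma of log)
INTENSITY_LEVELS: dict[str, tuple[float, float]] = {
    "neg": (40.0, 0.7),
    "dim": (500.0, 0.5),
    "pos": (4000.0, 0.5),
    "bright": (15000.0, 0.5),
}

#: per-case multiplicative intensity variation (sigma of log), positives only
CASE_INTENSITY_SIGMA = 0.25
CASE_SSC_SIGMA = 0.15
#: per-case fraction of blasts expressing an intermediate-rate antigen
PARTIAL_FRACTION_RANGE = (0.25, 0.65)

#: background composition of the non-blast compartment; the erythroid
#: fraction (CD45-negative nucleated red cells) anchors the bottom of the
#: CD45 display scale the way it does in real marrow
BACKGROUND_MIX = {
    "lymphocyte": 0.35,
    "monocyte": 0.20,
    "granulocyte": 0.35,
    "erythroid": 0.10,
}

# scatter levels: (median, sigma of log)
SSC_LEVELS = {
    "blast_hyper": (12000.0, 0.25),
    "blast_micro": (5000.0, 0.25),
    "blast_non_apl": (3500.0, 0.25),
    "lymphocyte": (1200.0, 0.25),
    "monocyte": (3000.0, 0.25),
    "granulocyte": (15000.0, 0.25),
    "erythroid": (600.0, 0.3),
}
FSC_LEVELS = {
    "blast": (9000.0, 0.2),
    "lymphocyte": (4000.0, 0.2),
    "monocyte": (7000.0, 0.2),
    "granulocyte": (8000.0, 0.2),
    "erythroid": (5000.0, 0.25),
}
CD45_LEVELS = {
    "blast": (1000.0, 0.3),
    "lymphocyte": (20000.0, 0.3),
    "monocyte": (15000.0, 0.3),
    "granulocyte": (8000.0, 0.25),
    "erythroid": (40.0, 0.7),  # negative
}


@dataclass(frozen=True)
class PhenotypeSpec:
    """Case-level phenotype model for one group.

    ``marker_probability`` holds the case-level probability that a case of
    this group is positive for each marker (0 and 1 are hard constraints);
    ``full_level`` the intensity level used when a constraint marker is
    positive (intermediate-rate markers always express at ``"dim"``).
    ``blast_fraction_range`` is sampled uniformly per case.
    """

    name: str
    marker_probability: dict[str, float]
    full_level: dict[str, str]
    ssc_level: str
    blast_fraction_range: tuple[float, float]
    background_mix: dict[str, float] = field(default_factory=lambda: dict(BACKGROUND_MIX))

    def __post_init__(self) -> None:
        for m, p in self.marker_probability.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{self.name}: probability for {m} outside [0,1]")
        total = sum(self.background_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"{self.name}: background mix sums to {total}")


_APL_BLAST_RANGE = (0.266, 0.875)
_NON_APL_BLAST_RANGE = (0.207, 0.829)

# characteristic level of each marker when expressed as a hard constraint
_FULL_LEVEL = {
    "CD117": "bright", "CD34": "bright", "CD33": "bright", "CD13": "bright",
    "CYMPO": "bright", "CD38": "pos", "CD123": "pos", "CD2": "pos",
    "CYFXIIIA": "pos",
}

_HYPER_PROBS = {
    "CD117": 1.0, "CD34": 0.0, "HLADR": 0.0, "CD33": 1.0, "CD13": 1.0,
    "CYMPO": 1.0, "CD14": 0.0, "CD11B": 0.0, "CD64": 0.5, "CD4": 0.0,
    "CD15": 0.0, "CD123": 0.0, "CD56": 0.17, "CD38": 1.0, "CD7": 0.0,
    "CD2": 0.17, "CYFXIIIA": 1.0, "CD71": 0.5, "CD10": 0.0, "CD16": 0.0,
    "CD300E": 0.0,
}
_MICRO_PROBS = dict(_HYPER_PROBS, CD34=1.0, CD123=1.0, CD56=0.0, CD7=0.5, CD2=1.0)
_NON_APL_PROBS = {
    "CD117": 1.0, "CD34": 0.0, "HLADR": 0.58, "CD33": 1.0, "CD13": 1.0,
    "CYMPO": 0.83, "CD14": 0.42, "CD11B": 0.42, "CD64": 0.42, "CD4": 0.42,
    "CD15": 0.42, "CD123": 0.75, "CD56": 0.25, "CD38": 1.0, "CD7": 0.25,
    "CD2": 0.0, "CYFXIIIA": 0.75, "CD71": 0.5, "CD10": 0.0, "CD16": 0.2,
    "CD300E": 0.42,
}

# background population profiles: marker -> (fraction expressing, level)
_BACKGROUND_PROFILES: dict[str, dict[str, tuple[float, str]]] = {
    "lymphocyte": {
        "CD2": (0.85, "pos"), "CD7": (0.85, "pos"), "CD4": (0.50, "pos"),
        "CD38": (0.60, "pos"), "HLADR": (0.15, "pos"), "CD56": (0.10, "pos"),
        "CD16": (0.10, "pos"),
    },
    "monocyte": {
        "CD14": (1.0, "bright"), "CD64": (1.0, "bright"), "CD33": (1.0, "bright"),
        "CD11B": (1.0, "pos"), "CD4": (1.0, "pos"), "HLADR": (1.0, "pos"),
        "CD13": (1.0, "pos"), "CD300E": (1.0, "pos"), "CD38": (1.0, "pos"),
        "CD123": (0.30, "pos"), "CYMPO": (1.0, "dim"), "CD15": (0.30, "dim"),
        "CD71": (0.30, "dim"), "CD16": (0.20, "pos"), "CYFXIIIA": (1.0, "pos"),
    },
    "granulocyte": {
        "CD13": (1.0, "pos"), "CD16": (0.90, "bright"), "CD15": (1.0, "bright"),
        "CD11B": (1.0, "bright"), "CD10": (0.70, "pos"), "CD64": (0.30, "dim"),
        "CD33": (1.0, "pos"), "CYMPO": (1.0, "bright"), "CD38": (0.30, "dim"),
        "CD71": (0.20, "dim"), "CD123": (0.10, "dim"),
    },
    "erythroid": {
        "CD71": (0.90, "bright"),
    },
}

GROUPS = ("hypergranular", "microgranular", "non_apl")


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """Shipped phenotype specs for the three study groups."""
    return {
        "hypergranular": PhenotypeSpec(
            name="hypergranular", marker_probability=dict(_HYPER_PROBS),
            full_level=dict(_FULL_LEVEL), ssc_level="blast_hyper",
            blast_fraction_range=_APL_BLAST_RANGE,
        ),
        "microgranular": PhenotypeSpec(
            name="microgranular", marker_probability=dict(_MICRO_PROBS),
            full_level=dict(_FULL_LEVEL), ssc_level="blast_micro",
            blast_fraction_range=_APL_BLAST_RANGE,
        ),
        "non_apl": PhenotypeSpec(
            name="non_apl", marker_probability=dict(_NON_APL_PROBS),
            full_level=dict(_FULL_LEVEL), ssc_level="blast_non_apl",
            blast_fraction_range=_NON_APL_BLAST_RANGE,
        ),
    }


@dataclass
class SyntheticCase:
    """One simulated patient: four tubes plus the generating truth."""

    case_id: str
    group: str
    tubes: dict[int, EventMatrix]
    marker_status: dict[str, bool]
    marker_fraction: dict[str, float]  # expressing blast fraction per positive marker
    blast_fraction: float
    seed: int

    @property
    def n_events(self) -> int:
        return next(iter(self.tubes.values())).n_events


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return median * np.exp(sigma * rng.standard_normal(n))


def simulate_case(
    spec: PhenotypeSpec,
    panel: PanelConfig | None = None,
    n_events: int = ACQUISITION_EVENTS,
    seed: int = 0,
    case_id: str | None = None,
    status_override: dict[str, bool] | None = None,
) -> SyntheticCase:
    """Simulate one case: all panel tubes with truth-labelled populations.

    Case-level marker statuses are drawn once (Bernoulli per marker) and
    shared across tubes; the blast count is an exact allocation
    (``round(fraction * n_events)``), not a binomial draw.  Event
    intensities are independent between tubes, the way separate stained
    aliquots are.  ``status_override`` pins selected case-level statuses
    (used by :func:`simulate_cohort` to reproduce cohort-level marker
    frequencies exactly) without disturbing the random stream.
    """
    panel = panel or default_panel()
    if n_events < 1000:
        raise InputError("simulate_case needs n_events >= 1000")
    seed = int(seed)
    rng = np.random.default_rng(seed)
    case_id = case_id or f"{spec.name}-{seed}"

    all_markers = sorted({normalize_marker(m) for t in panel.tubes for m in t.markers})
    unknown = [m for m in all_markers
               if m != "CD45" and m not in spec.marker_probability]
    if unknown:
        raise ConfigurationError(
            f"panel markers without phenotype specification: {unknown}"
        )

    status_override = {normalize_marker(k): bool(v)
                       for k, v in (status_override or {}).items()}

    # case-level draws, in fixed (sorted) marker order for determinism
    status: dict[str, bool] = {}
    fraction: dict[str, float] = {}
    case_factor: dict[str, float] = {}
    for m in all_markers:
        if m == "CD45":
            status[m], fraction[m] = True, 1.0
        else:
            p = spec.marker_probability[m]
            if p <= 0.0:
                status[m] = False
            elif p >= 1.0:
                status[m] = True
            else:
                status[m] = bool(rng.random() < p)
            if m in status_override:
                status[m] = status_override[m]
            intermediate = 0.0 < p < 1.0
            fraction[m] = (
                float(rng.uniform(*PARTIAL_FRACTION_RANGE)) if (status[m] and intermediate)
                else (1.0 if status[m] else 0.0)
            )
        case_factor[m] = float(np.exp(CASE_INTENSITY_SIGMA * rng.standard_normal()))
    ssc_factor = float(np.exp(CASE_SSC_SIGMA * rng.standard_normal()))
    blast_fraction = float(rng.uniform(*spec.blast_fraction_range))

    # exact population allocation
    n_blasts = int(round(blast_fraction * n_events))
    n_rest = n_events - n_blasts
    counts = {"blast": n_blasts}
    pops = sorted(spec.background_mix)
    assigned = 0
    for i, popname in enumerate(pops):
        if i == len(pops) - 1:
            counts[popname] = n_rest - assigned
        else:
            c = int(round(spec.background_mix[popname] * n_rest))
            counts[popname] = c
            assigned += c

    def marker_column(pop: str, marker_key: str, n: int, tube_rng) -> np.ndarray:
        neg_med, neg_sig = INTENSITY_LEVELS["neg"]
        col = _lognormal(tube_rng, neg_med, neg_sig, n)
        if n == 0:
            return col
        if pop == "blast":
            if marker_key == "CD45":
                med, sig = CD45_LEVELS["blast"]
                return _lognormal(tube_rng, med * case_factor[marker_key], sig, n)
            if status[marker_key]:
                p = spec.marker_probability[marker_key]
                level = spec.full_level.get(marker_key, "pos") if p >= 1.0 else "dim"
                med, sig = INTENSITY_LEVELS[level]
                f = fraction[marker_key]
                n_pos = int(round(f * n))
                pos_idx = tube_rng.permutation(n)[:n_pos]
                col[pos_idx] = _lognormal(
                    tube_rng, med * case_factor[marker_key], sig, n_pos
                )
            return col
        # background populations
        if marker_key == "CD45":
            med, sig = CD45_LEVELS[pop]
            return _lognormal(tube_rng, med, sig, n)
        profile = _BACKGROUND_PROFILES[pop].get(marker_key)
        if profile is not None:
            f, level = profile
            med, sig = INTENSITY_LEVELS[level]
            n_pos = int(round(f * n))
            pos_idx = tube_rng.permutation(n)[:n_pos]
            col[pos_idx] = _lognormal(tube_rng, med, sig, n_pos)
        return col

    tubes: dict[int, EventMatrix] = {}
    for tube in panel.tubes:
        tube_rng = np.random.default_rng([seed, tube.tube_id])
        blocks: list[np.ndarray] = []
        pop_labels: list[np.ndarray] = []
        for pop in ["blast"] + pops:
            n = counts[pop]
            if pop == "blast":
                ssc_med, ssc_sig = SSC_LEVELS[spec.ssc_level]
                ssc_med *= ssc_factor
                fsc_med, fsc_sig = FSC_LEVELS["blast"]
            else:
                ssc_med, ssc_sig = SSC_LEVELS[pop]
                fsc_med, fsc_sig = FSC_LEVELS[pop]
            cols = [
                _lognormal(tube_rng, fsc_med, fsc_sig, n),
                _lognormal(tube_rng, ssc_med, ssc_sig, n),
            ]
            for marker in tube.markers:
                cols.append(marker_column(pop, normalize_marker(marker), n, tube_rng))
            blocks.append(np.column_stack(cols))
            pop_labels.append(np.full(n, pop, dtype=object))
        values = np.vstack(blocks)
        tubes[tube.tube_id] = EventMatrix(
            values=values,
            channels=tube.channels,
            markers=tube.marker_map,
            labels={
                "case_id": np.full(n_events, case_id, dtype=object),
                "population": np.concatenate(pop_labels),
            },
            metadata={"group": spec.name, "seed": seed, "tube_id": tube.tube_id},
        )

    return SyntheticCase(
        case_id=case_id,
        group=spec.name,
        tubes=tubes,
        marker_status={m: status[m] for m in all_markers},
        marker_fraction={m: fraction[m] for m in all_markers},
        blast_fraction=blast_fraction,
        seed=seed,
    )


def derive_case_seed(master_seed: int, index: int) -> int:
    """Deterministic, collision-free per-case seed below 2**31."""
    return int((int(master_seed) * 100_003 + 7_919 * index + 1) % (2**31))


def simulate_cohort(
    n_hypergranular: int,
    n_microgranular: int,
    n_non_apl: int,
    panel: PanelConfig | None = None,
    n_events: int = ACQUISITION_EVENTS,
    master_seed: int = 0,
    phenotypes: dict[str, PhenotypeSpec] | None = None,
    exact_frequencies: bool = True,
) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Simulate a labelled cohort; returns the cases and a manifest table.

    Per-case seeds derive deterministically from ``master_seed``; the
    manifest records case id, group, seed, blast fraction and every
    case-level marker status.

    With ``exact_frequencies`` (default) the number of positive cases per
    intermediate-rate marker within each group equals ``round(p * n)``,
    assigned to cases by a seeded permutation — the phenotype table's
    percentages are a cohort composition (17% of 6 cases means exactly one
    positive case), so a cohort that reproduces the study must contain each
    variant.  Set it to False for fully independent per-case Bernoulli
    draws.
    """
    if min(n_hypergranular, n_microgranular, n_non_apl) < 0:
        raise InputError("group sizes must be >= 0")
    panel = panel or default_panel()
    phenotypes = phenotypes or default_phenotypes()
    plan = (
        [("hypergranular", i) for i in range(n_hypergranular)]
        + [("microgranular", i) for i in range(n_microgranular)]
        + [("non_apl", i) for i in range(n_non_apl)]
    )
    sizes = {"hypergranular": n_hypergranular, "microgranular": n_microgranular,
             "non_apl": n_non_apl}
    overrides: dict[str, list[dict[str, bool]]] = {}
    if exact_frequencies:
        alloc_rng = np.random.default_rng([int(master_seed) % (2**31), 9173])
        for group, n_group in sizes.items():
            spec = phenotypes[group]
            per_case: list[dict[str, bool]] = [dict() for _ in range(n_group)]
            for m in sorted(spec.marker_probability):
                p = spec.marker_probability[m]
                if not (0.0 < p < 1.0) or n_group == 0:
                    continue
                n_pos = int(round(p * n_group))
                order = alloc_rng.permutation(n_group)
                for rank, case_idx in enumerate(order):
                    per_case[case_idx][m] = rank < n_pos
            overrides[group] = per_case
    cases: list[SyntheticCase] = []
    rows: list[dict] = []
    for idx, (group, gi) in enumerate(plan):
        seed = derive_case_seed(master_seed, idx)
        case = simulate_case(
            phenotypes[group], panel=panel, n_events=n_events, seed=seed,
            case_id=f"{group.upper()}{gi + 1:02d}",
            status_override=overrides.get(group, [{}] * (gi + 1))[gi],
        )
        cases.append(case)
        row = {
            "case_id": case.case_id,
            "group": group,
            "seed": seed,
            "blast_fraction": case.blast_fraction,
        }
        row.update({f"status_{m}": int(v) for m, v in case.marker_status.items()})
        rows.append(row)
    columns = None
    if not rows:  # keep an empty manifest schematically valid
        columns = ["case_id", "group", "seed", "blast_fraction"]
    manifest = pd.DataFrame(rows, columns=columns)
    return cases, manifest


def write_fcs(case: SyntheticCase, directory) -> list[Path]:
    """Write one FCS 3.1 file per tube plus per-tube truth-label sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for tube_id, em in sorted(case.tubes.items()):
        path = directory / f"{case.case_id}_tube{tube_id}.fcs"
        write_fcs_file(
            path,
            em.values,
            channels=em.channels,
            markers=em.markers,
            extra_keywords={"CASE_ID": case.case_id, "GROUP": case.group,
                            "TUBE_ID": str(tube_id)},
        )
        sidecar = directory / f"{case.case_id}_tube{tube_id}_labels.csv"
        pd.DataFrame({
            "population": case.tubes[tube_id].labels["population"],
        }).to_csv(sidecar, index=False)
        paths.append(path)
    return paths
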