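"""Synthetic data generation with the statistical structure the
chronological analysis assumes.

Every stage of the pipeline can be exercised without any external data:
the generator draws a ground truth (diet proportions, birth and death
years, a family tree, a stratified deposit sequence, a true reservoir
offset) and then pushes it through the same probability model the
inference inverts — isotope measurements through the mixing likelihood
with the standard trophic enrichment factors, radiocarbon measurements
through the mixed calibration curve at the true marine fraction and
Delta-R.  All outputs are deterministic functions of (truth, seed).

The ``chincha-like`` preset mirrors the study conditions this package
is built around: 30 dated individuals and 43 determinations split over
a lower-valley complex (a stratified room sequence with charcoal
outliers and an ossuary holding a four-member family) and a set of
middle-valley burials grouped only as a uniform phase.

Default source tracer moments are order-of-magnitude realistic for
coastal Peru (marine fauna high in d15N, C4 plants high in d13C); they
are configuration, not biology claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcurve import (
    CalibrationCurve,
    CurveError,
    MixedCurve,
    RadiocarbonDetermination,
    ReservoirOffset,
    mix_curves,
    shift_marine,
)
from .chrono import (
    ChronoModel,
    LifeEvents,
    ModelDate,
    Phase,
    StratSequence,
    assemble_model,
    lifespan_events,
)
from .diet import (
    SOURCE_ORDER,
    DietHistogram,
    IsotopeSample,
    SourceCategory,
    TrophicEnrichment,
)
from .pedigree import FamilyTree, GenerationGap, pedigree_to_constraints

__all__ = [
    "DEFAULT_SOURCE_CONFIG",
    "TrueIndividual",
    "TrueSample",
    "ScenarioTruth",
    "default_sources",
    "simulate_isotopes",
    "simulate_chronology",
    "make_toy_curve",
    "chincha_like",
    "family_scenario",
    "build_model",
    "true_histogram",
]

#: per-source (mean_d13C, mean_d15N, sd_d13C, sd_d15N) in permil
DEFAULT_SOURCE_CONFIG: dict[str, tuple[float, float, float, float]] = {
    "C3_plants": (-26.5, 4.0, 1.5, 2.0),
    "C4_plants": (-11.5, 6.0, 1.0, 2.0),
    "terrestrial_fauna": (-18.5, 6.0, 1.5, 1.5),
    "marine_fauna": (-12.5, 16.0, 1.0, 2.0),
}


@dataclass
class TrueIndividual:
    """Ground truth for one (possibly undated) person."""

    id: str
    group: str  # "middle" | "ossuary" | "mortuary" | "final" | "unsampled"
    birth_ad: float
    age_at_death: float | None
    age_interval: tuple[float, float] | None  # osteological estimate
    diet: np.ndarray | None  # 4-simplex in SOURCE_ORDER, None if unsampled
    tissue: str = "second_molar"
    sigma_meas: float = 20.0

    @property
    def death_ad(self) -> float | None:
        return None if self.age_at_death is None else self.birth_ad + self.age_at_death

    @property
    def marine(self) -> float:
        return float(self.diet[SOURCE_ORDER.index("marine_fauna")])


@dataclass
class TrueSample:
    """Ground truth for one non-human dated sample."""

    lab_code: str
    event: str
    year_ad: float  # true deposition year of the context
    material: str = "plant"
    sigma_meas: float = 20.0
    old_wood_shift: float = 0.0  # years the sample pre-dates its context


@dataclass
class ScenarioTruth:
    """Everything the generator knows and the inference must recover."""

    delta_r: float
    individuals: list[TrueIndividual]
    samples: list[TrueSample] = field(default_factory=list)
    family_tree: FamilyTree | None = None
    sequence_groups: list[list[str]] = field(default_factory=list)
    phases: dict[str, list[str]] = field(default_factory=dict)
    window_ad: tuple[float, float] = (1000.0, 1800.0)

    @property
    def sampled(self) -> list[TrueIndividual]:
        return [i for i in self.individuals if i.diet is not None]


def default_sources() -> dict[str, tuple[float, float, float, float]]:
    return dict(DEFAULT_SOURCE_CONFIG)


# ---------------------------------------------------------------------------
# isotopes


def simulate_isotopes(
    truth: ScenarioTruth,
    sources_config: dict[str, tuple[float, float, float, float]] | None = None,
    seed: int = 0,
    n_source_samples: int = 12,
    tef: TrophicEnrichment | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw source reference samples and consumer tracer values.

    Consumers follow the process-error mixing likelihood at their true
    diet proportions; QC columns are filled with passing values so the
    collagen screen keeps every simulated sample.  Returns
    ``(consumers, sources)`` data frames in the CSV schemas the pipeline
    reads.
    """
    cfg = sources_config or DEFAULT_SOURCE_CONFIG
    tef = tef or TrophicEnrichment()
    for ind in truth.sampled:
        p = np.asarray(ind.diet, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"{ind.id}: diet proportions must lie on the 4-simplex")
    rng = np.random.default_rng(seed)
    src_rows = []
    for name in SOURCE_ORDER:
        m13, m15, s13, s15 = cfg[name]
        for i in range(n_source_samples):
            src_rows.append(
                {
                    "category": name,
                    "id": f"{name}_{i}",
                    "d13C": rng.normal(m13, s13),
                    "d15N": rng.normal(m15, s15),
                    "cn_ratio": round(rng.uniform(3.15, 3.45), 2),
                    "pctC": round(rng.uniform(30, 45), 1),
                    "pctN": round(rng.uniform(11, 16), 1),
                }
            )
    mu = np.array([[cfg[n][0], cfg[n][1]] for n in SOURCE_ORDER])
    var = np.array([[cfg[n][2] ** 2, cfg[n][3] ** 2] for n in SOURCE_ORDER])
    lam = tef.mean_matrix()
    tau2 = tef.sd_matrix() ** 2
    cons_rows = []
    for ind in truth.sampled:
        p = np.asarray(ind.diet, dtype=float)
        mean = p @ (mu + lam)
        sd = np.sqrt((p**2) @ (var + tau2))
        x = rng.normal(mean, sd)
        cons_rows.append(
            {
                "id": ind.id,
                "d13C": x[0],
                "d15N": x[1],
                "cn_ratio": round(rng.uniform(3.15, 3.35), 2),
                "pctC": round(rng.uniform(30, 45), 1),
                "pctN": round(rng.uniform(11, 16), 1),
                "tissue": ind.tissue,
            }
        )
    return pd.DataFrame(cons_rows), pd.DataFrame(src_rows)


# ---------------------------------------------------------------------------
# radiocarbon


def simulate_chronology(
    truth: ScenarioTruth,
    terrestrial: CalibrationCurve,
    marine: CalibrationCurve,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one radiocarbon determination per dated individual and
    non-human sample.

    Human measurements come from the mixed-curve likelihood at the true
    tissue-formation year, marine fraction and Delta-R; non-human
    samples from the terrestrial curve at their context year plus any
    old-wood shift.  Raises :class:`~tidechron.calcurve.CurveError`
    when a true event falls outside the curve span.
    """
    rng = np.random.default_rng(seed)
    shifted = shift_marine(marine, ReservoirOffset("fixed", mean=truth.delta_r, sd=0.0))
    rows = []
    for k, ind in enumerate(truth.sampled):
        offset = rng.normal(11.0, 1.0) if ind.tissue == "second_molar" else rng.normal(15.0, 5.0)
        theta_ad = ind.birth_ad + offset
        theta_bp = 1950.0 - theta_ad
        curve: MixedCurve = mix_curves(terrestrial, shifted, ind.marine)
        lo, hi = curve.span
        if not lo <= theta_bp <= hi:
            raise CurveError(f"{ind.id}: true tissue date {theta_bp} cal BP outside curve span")
        mu = float(curve.mu(theta_bp))
        sd = float(np.sqrt(ind.sigma_meas**2 + float(curve.sigma_at(theta_bp)) ** 2))
        rows.append(
            {
                "lab_code": f"SYN-{1000 + k}",
                "individual": ind.id,
                "event": f"tissue:{ind.id}",
                "c14_age": round(float(rng.normal(mu, sd))),
                "sigma": ind.sigma_meas,
                "material": "human bone",
                "tissue": ind.tissue,
                "group": ind.group,
                "charcoal_outlier": False,
            }
        )
    for s in truth.samples:
        theta_bp = 1950.0 - s.year_ad + s.old_wood_shift
        lo, hi = terrestrial.span
        if not lo <= theta_bp <= hi:
            raise CurveError(f"{s.lab_code}: true date {theta_bp} cal BP outside curve span")
        mu = float(terrestrial.mu(theta_bp))
        sd = float(np.sqrt(s.sigma_meas**2 + float(terrestrial.sigma_at(theta_bp)) ** 2))
        rows.append(
            {
                "lab_code": s.lab_code,
                "individual": "",
                "event": s.event,
                "c14_age": round(float(rng.normal(mu, sd))),
                "sigma": s.sigma_meas,
                "material": s.material,
                "tissue": "",
                "group": "sequence",
                "charcoal_outlier": s.old_wood_shift > 0,
            }
        )
    return pd.DataFrame(rows)


def make_toy_curve(
    nodes: list[tuple[float, float, float]],
    name: str = "toy",
    kind: str = "terrestrial",
    step: float = 5.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> CalibrationCurve:
    """Build a small synthetic curve from ``(calBP, mu, sigma)`` nodes.

    Nodes are linearly interpolated onto a regular grid; optional seeded
    ``jitter`` (14C years, sd) roughens mu to create wiggles and
    plateaus for oracle tests.  Calendar ages must be strictly monotone.
    """
    arr = np.asarray(nodes, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
        raise ValueError("need at least two (calBP, mu, sigma) nodes")
    cal = arr[:, 0]
    d = np.diff(cal)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("node calendar ages must be strictly monotone")
    if d[0] < 0:
        arr = arr[::-1]
        cal = arr[:, 0]
    grid = np.arange(cal[0], cal[-1] + step / 2, step)
    mu = np.interp(grid, cal, arr[:, 1])
    sig = np.interp(grid, cal, arr[:, 2])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        mu = mu + rng.normal(0.0, jitter, size=mu.size)
    return CalibrationCurve(name, grid, mu, sig, kind=kind)


# ---------------------------------------------------------------------------
# presets


def _family_truth(rng: np.random.Generator, gm_birth: float) -> tuple[FamilyTree, dict[str, float]]:
    """Fig-2-shaped family: grandparents -> (mother, uncle); mother ->
    two maternal half-brothers; uncle -> one child; the elder brother
    fathers a daughter.  Returns the tree over sampled ids F12, F14,
    F27, F34 plus placeholders, and true birth years."""
    tree = FamilyTree()
    tree.set_parent("?M", "?GM", "mother")
    tree.set_parent("?U", "?GM", "mother")
    tree.set_parent("F12", "?M", "mother")
    tree.set_parent("F27", "?M", "mother")
    tree.set_parent("F34", "?U", "father")
    tree.set_parent("F14", "F12", "father")
    births = {"?GM": gm_birth}
    births["?M"] = births["?GM"] + rng.normal(24, 6)
    births["?U"] = births["?GM"] + rng.normal(24, 6)
    births["F12"] = births["?M"] + rng.normal(24, 6)
    births["F27"] = births["?M"] + rng.normal(24, 6)
    births["F34"] = births["?U"] + rng.normal(28, 7)
    births["F14"] = births["F12"] + rng.normal(28, 7)
    return tree, births


def _draw_diet(rng: np.random.Generator) -> np.ndarray:
    # right-skewed marine fraction with real spread (farmers through
    # fisherfolk); the remaining mass splits over the terrestrial sources
    m = float(rng.beta(1.6, 4.0))
    rest = rng.dirichlet((2.0, 2.0, 2.0)) * (1.0 - m)
    return np.append(rest, m)


def chincha_like(seed: int = 0, delta_r: float = -300.0) -> ScenarioTruth:
    """The full study-scale preset: 30 dated individuals and 43
    determinations, one ossuary family of four, a stratified lower-valley
    sequence with two old-wood charcoal dates, and a middle-valley
    uniform phase."""
    rng = np.random.default_rng(seed)
    individuals: list[TrueIndividual] = []
    samples: list[TrueSample] = []

    def osteo_interval(age: float) -> tuple[float, float]:
        # an osteological bracket that contains the true age, as a
        # competent assessment would
        lo = max(15.0, 5.0 * np.floor((age - rng.uniform(4, 10)) / 5.0))
        hi = 5.0 * np.ceil((age + rng.uniform(4, 10)) / 5.0)
        return (lo, hi)

    def person(pid: str, group: str, birth: float) -> TrueIndividual:
        age = float(np.clip(rng.normal(45, 12), 18, 75))
        return TrueIndividual(
            pid, group, birth, age, osteo_interval(age), _draw_diet(rng)
        )

    # middle valley: 13 individuals, deaths spread over a long phase
    for i in range(13):
        birth = rng.uniform(1260, 1500)
        individuals.append(person(f"MV{i:02d}", "middle", birth))

    # lower valley ossuary: 13 individuals incl. the family of four
    tree, births = _family_truth(rng, gm_birth=rng.uniform(1270, 1300))
    for pid in ("F12", "F14", "F27", "F34"):
        individuals.append(person(pid, "ossuary", births[pid]))
    for pid in ("?GM", "?M", "?U"):
        individuals.append(
            TrueIndividual(pid, "unsampled", births[pid], None, None, None)
        )
    for i in range(9):
        individuals.append(person(f"OS{i:02d}", "ossuary", rng.uniform(1290, 1400)))

    # main-room stratigraphic sequence: non-human anchors and 4 humans
    levels = [
        ("L10_11", 3, 1270, 1285, 0),
        ("L7_8", 4, 1290, 1310, 0),
        ("kilns", 3, 1318, 1332, 2),  # two old-wood charcoal dates
        ("camelid", 2, 1340, 1352, 0),
    ]
    lab = 100
    sequence_groups: list[list[str]] = []
    for name, n, lo, hi, n_charcoal in levels:
        grp = []
        for i in range(n):
            ev = f"s:{name}_{i}"
            shift = 0.0
            material = "plant"
            if i < n_charcoal:
                material = "charcoal"
                shift = float(np.minimum(rng.exponential(1.0) + 0.05, 10.0) * 10.0 ** rng.uniform(0.5, 1.5))
            samples.append(TrueSample(f"SYN-{lab}", ev, rng.uniform(lo, hi), material, 20.0, shift))
            grp.append(ev)
            lab += 1
        sequence_groups.append(grp)
    # level-4 mortuary program: four dated humans, deaths in order
    mortuary = []
    for i in range(4):
        birth = rng.uniform(1310, 1330)
        ind = person(f"MR{i:02d}", "mortuary", birth)
        # force deaths into the level window
        ind.age_at_death = float(np.clip(rng.uniform(1355, 1375) - birth, 20, 70))
        ind.age_interval = osteo_interval(ind.age_at_death)
        individuals.append(ind)
        mortuary.append(f"death:{ind.id}")
    sequence_groups.append(mortuary)
    samples.append(TrueSample(f"SYN-{lab}", "s:final_0", rng.uniform(1390, 1405), "plant", 20.0, 0.0))
    sequence_groups.append(["s:final_0"])

    phases = {
        "middle_valley": [f"death:MV{i:02d}" for i in range(13)],
        "ossuary": [f"death:{pid}" for pid in ("F12", "F14", "F27", "F34")]
        + [f"death:OS{i:02d}" for i in range(9)],
    }
    return ScenarioTruth(
        delta_r=delta_r,
        individuals=individuals,
        samples=samples,
        family_tree=tree,
        sequence_groups=sequence_groups,
        phases=phases,
        window_ad=(1000.0, 1800.0),
    )


def family_scenario(seed: int = 0, delta_r: float = -300.0) -> ScenarioTruth:
    """Compact preset: the four-member family plus terrestrial anchors
    bracketing their deaths; used for pedigree-precision experiments."""
    rng = np.random.default_rng(seed)
    tree, births = _family_truth(rng, gm_birth=rng.uniform(1270, 1300))
    individuals = []
    for pid in ("F12", "F14", "F27", "F34"):
        age = float(np.clip(rng.normal(45, 10), 20, 70))
        lo = max(15.0, 5.0 * np.floor((age - rng.uniform(0, 8)) / 5.0))
        # coastal family: every member ate appreciable marine protein, so
        # each stand-alone calibration is diet-limited, the regime the
        # generational constraints are meant to rescue
        m = float(rng.uniform(0.15, 0.45))
        diet = np.append(rng.dirichlet((2.0, 2.0, 2.0)) * (1.0 - m), m)
        individuals.append(
            TrueIndividual(pid, "ossuary", births[pid], age, (lo, lo + 15.0), diet)
        )
    for pid in ("?GM", "?M", "?U"):
        individuals.append(TrueIndividual(pid, "unsampled", births[pid], None, None, None))
    deaths = [i.death_ad for i in individuals if i.death_ad is not None]
    samples = [
        TrueSample("SYN-900", "s:below", min(deaths) - rng.uniform(25, 40), "plant", 20.0, 0.0),
        TrueSample("SYN-901", "s:above", max(deaths) + rng.uniform(25, 40), "plant", 20.0, 0.0),
    ]
    sequence_groups = [
        ["s:below"],
        [f"death:{pid}" for pid in ("F12", "F14", "F27", "F34")],
        ["s:above"],
    ]
    return ScenarioTruth(
        delta_r=delta_r,
        individuals=individuals,
        samples=samples,
        family_tree=tree,
        sequence_groups=sequence_groups,
        phases={},
        window_ad=(1000.0, 1800.0),
    )


def true_histogram(marine_frac: float, sd: float = 0.03, n: int = 10_000, seed: int = 0) -> DietHistogram:
    """Histogram prior concentrated near a known marine fraction; a
    stand-in for a fitted diet posterior in chronology-only tests."""
    rng = np.random.default_rng(seed)
    draws = np.clip(rng.normal(marine_frac, sd, size=n), 0.0, 0.999)
    counts, _ = np.histogram(draws * 100.0, bins=np.linspace(0, 100, 101))
    return DietHistogram(counts)


# ---------------------------------------------------------------------------
# model assembly from a scenario


def build_model(
    truth: ScenarioTruth,
    dates: pd.DataFrame,
    histograms: dict[str, DietHistogram],
    terrestrial: CalibrationCurve,
    marine: CalibrationCurve,
    delta_r_prior: ReservoirOffset | None = None,
    use_gaps: bool = True,
) -> ChronoModel:
    """Wire simulated (or real, same-schema) data into a ChronoModel.

    ``histograms`` maps individual id to a marine-diet histogram; ids
    missing from the map are treated as fully terrestrial.  Generational
    gaps come from the scenario's family tree unless ``use_gaps`` is
    false (the ablation used to measure their precision gain).
    """
    life_events: list[LifeEvents] = []
    for ind in truth.individuals:
        if ind.diet is None:
            life_events.append(lifespan_events(ind.id, None, None))
        else:
            life_events.append(lifespan_events(ind.id, ind.tissue, ind.age_interval))
    model_dates: list[ModelDate] = []
    for row in dates.itertuples(index=False):
        det = RadiocarbonDetermination(
            row.lab_code, float(row.c14_age), float(row.sigma),
            material=row.material, tissue=row.tissue or None,
        )
        hist = histograms.get(row.individual) if row.individual else None
        model_dates.append(
            ModelDate(det, row.event, histogram=hist, charcoal_outlier=bool(row.charcoal_outlier))
        )
    gaps: list[GenerationGap] = []
    if use_gaps and truth.family_tree is not None:
        gaps = pedigree_to_constraints(truth.family_tree)
    phases = [Phase(name, members) for name, members in truth.phases.items()]
    sequences = (
        [StratSequence("main_room", truth.sequence_groups)] if truth.sequence_groups else []
    )
    extra = sorted({s.event for s in truth.samples})
    return assemble_model(
        life_events=life_events,
        dates=model_dates,
        curve_terrestrial=terrestrial,
        curve_marine=marine,
        delta_r=delta_r_prior or ReservoirOffset("free", lower=-600.0, upper=200.0),
        gaps=gaps,
        phases=phases,
        sequences=sequences,
        extra_events=extra,
        window_ad=truth.window_ad,
    )
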