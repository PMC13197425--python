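"""Joint Bayesian chronological model for marine-influenced burials.

The model ties together, in one posterior:

* latent calendar events (tissue formation, birth, death, deposition,
  phase boundaries) on the cal BP scale,
* per-individual marine diet fractions ``m_i`` with the 100-bin
  posterior histograms from the diet mixing model as priors,
* a single free marine reservoir offset Delta-R shared by all samples,
* radiocarbon likelihoods through per-individual mixed calibration
  curves evaluated at the current ``(m_i, Delta-R)``,
* tissue-formation offsets (birth = tissue date - offset) and uniform
  age-at-death intervals (death = birth + age),
* generational-gap priors from a family tree (mothers 24 +/- 6,
  fathers 28 +/- 7 years old at a child's birth),
* stratigraphic sequences (strict order), uniform phases with free
  boundaries, and a charcoal ("old wood") outlier model under which a
  flagged sample may pre-date its context by ``eps * 10^u`` years with
  ``eps ~ Exp(1)`` truncated to (0, 10] per date and a shared
  ``u ~ Uniform(0, 3)``.

Inference is Metropolis-within-Gibbs with per-parameter adaptive random
walks (marine fractions use independence proposals from their histogram
priors); hard order constraints are enforced by rejection.  Agreement
indices compare each date's modeled marginal against its stand-alone
calibration, flagging values below 60%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

import arviz as az

from .calcurve import (
    CalendarDensity,
    CalibrationCurve,
    CurveError,
    RadiocarbonDetermination,
    ReservoirOffset,
    calibrate_single,
    mix_curves,
    shift_marine,
)
from .diet import DietHistogram
from .pedigree import GenerationGap

__all__ = [
    "DEFAULT_TISSUE_OFFSETS",
    "DEFAULT_WINDOW_AD",
    "TissueOffsetTable",
    "LifeEvents",
    "ModelDate",
    "Phase",
    "StratSequence",
    "ChronoModel",
    "PosteriorChains",
    "ModelValidationError",
    "McmcError",
    "lifespan_events",
    "assemble_model",
    "combine_determinations",
    "run_mcmc",
    "agreement_index",
    "agreement_indices",
]

#: tissue label -> (offset mean, offset sd) in years between birth and
#: tissue formation; second molar crown/root formation ~ age 11 +/- 1,
#: vomer and sphenoid fuse in early adulthood (informal 15 +/- 5)
DEFAULT_TISSUE_OFFSETS: dict[str, tuple[float, float]] = {
    "second_molar": (11.0, 1.0),
    "vomer": (15.0, 5.0),
    "sphenoid": (15.0, 5.0),
    "bone": (0.0, 0.0),
}

#: default calendar window for boundaries and latent events, AD scale
DEFAULT_WINDOW_AD = (500.0, 1800.0)


class ModelValidationError(ValueError):
    """The model references undeclared events or is internally contradictory."""


class McmcError(RuntimeError):
    """Sampling failed (non-convergence or a dead parameter); carries
    diagnostics when available."""

    def __init__(self, message: str, rhat: dict[str, float] | None = None):
        super().__init__(message)
        self.rhat = rhat or {}


class TissueOffsetTable:
    """Lookup from tissue label to a Normal(mean, sd) formation offset."""

    def __init__(self, extra: dict[str, tuple[float, float]] | None = None):
        self.table = dict(DEFAULT_TISSUE_OFFSETS)
        if extra:
            self.table.update(extra)

    def get(self, tissue: str) -> tuple[float, float]:
        try:
            return self.table[tissue]
        except KeyError:
            raise KeyError(
                f"no formation offset for tissue {tissue!r}; supply an explicit "
                f"override (known: {sorted(self.table)})"
            ) from None


@dataclass
class LifeEvents:
    """Linked latent events for one individual.

    ``birth = tissue_date - Normal(offset_mean, offset_sd)`` on the AD
    axis (equivalently ``birth_BP = tissue_BP + offset``) and
    ``death = birth + Uniform(age)``.  ``age_at_death`` may be None for
    undated placeholder relatives whose death is not modeled.
    """

    individual: str
    tissue: str | None
    offset: tuple[float, float]
    age_at_death: tuple[float, float] | None

    @property
    def tissue_event(self) -> str:
        return f"tissue:{self.individual}"

    @property
    def birth_event(self) -> str:
        return f"birth:{self.individual}"

    @property
    def death_event(self) -> str:
        return f"death:{self.individual}"


def lifespan_events(
    individual: str,
    tissue: str | None,
    age_at_death: tuple[float, float] | None,
    offsets: TissueOffsetTable | None = None,
    offset_override: tuple[float, float] | None = None,
) -> LifeEvents:
    """Build the tissue/birth/death event triple for one individual.

    Secondary dentine deposition is deliberately ignored (it adds only a
    few years and only for old individuals); the offset describes
    primary tissue formation age.
    """
    if offset_override is not None:
        off = offset_override
    elif tissue is not None:
        off = (offsets or TissueOffsetTable()).get(tissue)
    else:
        off = (0.0, 0.0)
    if age_at_death is not None and age_at_death[0] > age_at_death[1]:
        raise ValueError(f"{individual}: age_at_death min > max")
    return LifeEvents(individual, tissue, off, age_at_death)


@dataclass
class ModelDate:
    """One determination wired into the model.

    ``event`` names the latent calendar event the sample dates; human
    samples carry the individual's marine-diet ``histogram`` (or
    ``None`` for a fully terrestrial diet); ``charcoal_outlier`` flags
    dates allowed to pre-date their context ("old wood").
    """

    det: RadiocarbonDetermination
    event: str
    histogram: DietHistogram | None = None
    charcoal_outlier: bool = False


@dataclass
class Phase:
    """Uniform phase: members iid Uniform(start, end) with boundary
    prior proportional to 1/(end - start) on the model window."""

    name: str
    members: list[str]
    open_start: bool = False  # no lower boundary (mixed deposits)

    @property
    def start_event(self) -> str:
        return f"start:{self.name}"

    @property
    def end_event(self) -> str:
        return f"end:{self.name}"


@dataclass
class StratSequence:
    """Strict stratigraphic order: every event in ``groups[k]`` is older
    than every event in ``groups[k+1]``."""

    name: str
    groups: list[list[str]]


@dataclass
class ChronoModel:
    """Validated event graph plus curves and the Delta-R prior."""

    life_events: list[LifeEvents]
    dates: list[ModelDate]
    curve_terrestrial: CalibrationCurve
    curve_marine: CalibrationCurve
    delta_r: ReservoirOffset = field(default_factory=lambda: ReservoirOffset("free", lower=-600.0, upper=200.0))
    gaps: list[GenerationGap] = field(default_factory=list)
    phases: list[Phase] = field(default_factory=list)
    sequences: list[StratSequence] = field(default_factory=list)
    extra_events: list[str] = field(default_factory=list)
    window_ad: tuple[float, float] = DEFAULT_WINDOW_AD

    @property
    def window_bp(self) -> tuple[float, float]:
        """Model window as (young, old) in cal BP."""
        lo_ad, hi_ad = self.window_ad
        return 1950.0 - hi_ad, 1950.0 - lo_ad


def _known_events(model: ChronoModel) -> set[str]:
    known: set[str] = set(model.extra_events)
    for le in model.life_events:
        known.update((le.tissue_event, le.birth_event))
        if le.age_at_death is not None:
            known.add(le.death_event)
    for ph in model.phases:
        known.update((ph.start_event, ph.end_event))
    return known


def assemble_model(
    life_events: Sequence[LifeEvents],
    dates: Sequence[ModelDate],
    curve_terrestrial: CalibrationCurve,
    curve_marine: CalibrationCurve,
    delta_r: ReservoirOffset | None = None,
    gaps: Sequence[GenerationGap] = (),
    phases: Sequence[Phase] = (),
    sequences: Sequence[StratSequence] = (),
    extra_events: Sequence[str] = (),
    window_ad: tuple[float, float] = DEFAULT_WINDOW_AD,
) -> ChronoModel:
    """Validate and assemble the joint model.

    Every determination must date a declared event, phase and sequence
    members must be declared, and the hard order relations must be
    satisfiable (no cycles).  Raises :class:`ModelValidationError`
    listing all offenders.
    """
    model = ChronoModel(
        list(life_events), list(dates), curve_terrestrial, curve_marine,
        delta_r or ReservoirOffset("free", lower=-600.0, upper=200.0),
        list(gaps), list(phases), list(sequences), list(extra_events),
        tuple(window_ad),
    )
    problems: list[str] = []
    if not model.dates:
        problems.append("model has no determinations")
    known = _known_events(model)
    by_ind = {le.individual: le for le in model.life_events}
    for d in model.dates:
        if d.event not in known:
            problems.append(f"determination {d.det.lab_code} dates undeclared event {d.event!r}")
    for g in model.gaps:
        for ind in (g.parent, g.child):
            if ind not in by_ind:
                problems.append(f"generational gap references unknown individual {ind!r}")
    for ph in model.phases:
        for m in ph.members:
            if m not in known:
                problems.append(f"phase {ph.name!r} references undeclared event {m!r}")
    order_edges: list[tuple[str, str]] = []
    for sq in model.sequences:
        for grp in sq.groups:
            for m in grp:
                if m not in known:
                    problems.append(f"sequence {sq.name!r} references undeclared event {m!r}")
        for older, younger in zip(sq.groups, sq.groups[1:]):
            order_edges.extend((a, b) for a in older for b in younger)
    # contradictory hard orders = cycle in the older-than graph
    adj: dict[str, set[str]] = {}
    for a, b in order_edges:
        adj.setdefault(a, set()).add(b)
    state: dict[str, int] = {}

    def cyc(n: str) -> bool:
        state[n] = 1
        for nxt in adj.get(n, ()):
            s = state.get(nxt, 0)
            if s == 1 or (s == 0 and cyc(nxt)):
                return True
        state[n] = 2
        return False

    if any(state.get(n, 0) == 0 and cyc(n) for n in list(adj)):
        problems.append("sequence constraints contain a cycle (contradictory order)")
    if problems:
        raise ModelValidationError("; ".join(problems))
    return model


def combine_determinations(
    dets: Sequence[RadiocarbonDetermination],
) -> tuple[RadiocarbonDetermination, dict]:
    """Inverse-variance-weighted pool of repeat measurements of one event.

    Returns the pooled determination and a chi-square consistency report
    (``statistic``, ``df``, ``pvalue``, ``passed`` at the 5% level).
    """
    if len(dets) < 2:
        raise ValueError("combine_determinations needs at least 2 determinations")
    ages = np.array([d.age for d in dets])
    w = np.array([1.0 / d.sigma**2 for d in dets])
    mean = float((w * ages).sum() / w.sum())
    sigma = float(w.sum() ** -0.5)
    chi2 = float((w * (ages - mean) ** 2).sum())
    df = len(dets) - 1
    from scipy.stats import chi2 as chi2_dist

    pvalue = float(chi2_dist.sf(chi2, df))
    pooled = RadiocarbonDetermination(
        lab_code="+".join(d.lab_code for d in dets),
        age=mean,
        sigma=sigma,
        material=dets[0].material,
        tissue=dets[0].tissue,
        context=dets[0].context,
    )
    return pooled, {"statistic": chi2, "df": df, "pvalue": pvalue, "passed": pvalue >= 0.05}


# ---------------------------------------------------------------------------
# sampler internals


class _Param:
    __slots__ = (
        "name", "value", "kind", "lo", "hi", "step", "factors", "acc", "tries",
        "support", "indep_prob",
    )

    def __init__(self, name, value, kind, lo=-np.inf, hi=np.inf, step=10.0, indep_prob=0.0):
        self.name = name
        self.value = float(value)
        self.kind = kind  # "rw" | "hist" | "fixed"
        self.lo, self.hi = lo, hi
        self.step = step
        self.factors: list[int] = []
        self.acc = 0
        self.tries = 0
        # probability of a uniform independence proposal over [lo, hi]
        # instead of the random walk; jumps between calibration-curve
        # modes that a pure random walk crosses only slowly
        self.indep_prob = indep_prob


@dataclass
class PosteriorChains:
    """Per-parameter posterior draws, shaped (chains, draws)."""

    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    acceptance: dict[str, float]
    seed: int
    model: "ChronoModel | None" = None

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def event_draws(self, event: str) -> np.ndarray:
        """Flattened draws (cal BP) for any declared or derived event."""
        kind, _, ind = event.partition(":")
        if f"e:{event}" in self.draws:
            return self.flat(f"e:{event}")
        if kind == "tissue":
            return self.flat(f"t:{ind}")
        if kind == "birth":
            return self.flat(f"t:{ind}") + self.flat(f"o:{ind}")
        if kind == "death":
            return self.flat(f"t:{ind}") + self.flat(f"o:{ind}") - self.flat(f"a:{ind}")
        raise KeyError(f"unknown event {event!r}")


def _hist_prior_support(hist: DietHistogram) -> tuple[np.ndarray, np.ndarray]:
    w = hist.prior_weights()
    keep = w > 0
    return hist.bin_centers[keep], w[keep]


class _FastCurve:
    """Pre-tabulated 1-year lookup of a curve's mu and sigma over the
    sampling window; scalar linear interpolation without array overhead."""

    __slots__ = ("lo", "hi", "mu_tab", "sig_tab")

    def __init__(self, curve, lo: float, hi: float):
        c_lo, c_hi = curve.span
        self.lo = max(float(np.ceil(c_lo)), lo)
        self.hi = min(float(np.floor(c_hi)), hi)
        grid = np.arange(self.lo, self.hi + 1.0)
        self.mu_tab = np.asarray(curve.mu(grid), dtype=float)
        self.sig_tab = np.asarray(curve.sigma_at(grid), dtype=float)

    def mu_sig(self, theta: float):
        """(mu, sigma) at theta, or None outside the tabulated span."""
        x = theta - self.lo
        if x < 0.0 or theta > self.hi:
            return None
        i = int(x)
        if i >= self.mu_tab.size - 1:
            return float(self.mu_tab[-1]), float(self.sig_tab[-1])
        f = x - i
        mu = self.mu_tab[i] * (1.0 - f) + self.mu_tab[i + 1] * f
        sig = self.sig_tab[i] * (1.0 - f) + self.sig_tab[i + 1] * f
        return float(mu), float(sig)


def _build_state(model: ChronoModel, rng: np.random.Generator):
    """Initialize parameters and the factor graph for one chain."""
    terr, mar = model.curve_terrestrial, model.curve_marine
    win_lo_bp = 1950.0 - model.window_ad[1]
    win_hi_bp = 1950.0 - model.window_ad[0]
    # lookup span: window plus slack for boundaries and old-wood shifts
    fast_terr = _FastCurve(terr, win_lo_bp - 500.0, win_hi_bp + 1500.0)
    fast_mar = _FastCurve(mar, win_lo_bp - 500.0, win_hi_bp + 1500.0)

    params: dict[str, _Param] = {}
    factors: list[Callable[[], float]] = []

    def add_param(p: _Param) -> _Param:
        params[p.name] = p
        return p

    def add_factor(fn: Callable[[], float], names: Iterable[str]) -> None:
        idx = len(factors)
        factors.append(fn)
        for n in names:
            params[n].factors.append(idx)

    # Delta-R
    dr = model.delta_r
    if dr.mode == "free":
        add_param(
            _Param("dR", 0.5 * (dr.lower + dr.upper), "rw", dr.lower, dr.upper,
                   step=25.0, indep_prob=0.03)
        )
    else:
        add_param(_Param("dR", dr.mean, "fixed"))
    fixed_dr_var = dr.sd**2 if dr.mode == "fixed" else 0.0

    by_ind = {le.individual: le for le in model.life_events}

    # latent event parameters
    def init_event_guess(date: ModelDate) -> float:
        try:
            dens = calibrate_single(date.det, terr, window=(terr.span[0], terr.span[1]))
            return dens.median_bp()
        except CurveError:
            return 0.5 * (win_lo_bp + win_hi_bp)

    dated_events: dict[str, list[ModelDate]] = {}
    for d in model.dates:
        dated_events.setdefault(d.event, []).append(d)

    for le in model.life_events:
        guesses = [init_event_guess(d) for d in model.dates if d.event == le.tissue_event]
        guess = float(np.mean(guesses)) if guesses else 0.5 * (win_lo_bp + win_hi_bp)
        add_param(_Param(f"t:{le.individual}", guess, "rw", win_lo_bp - 200, win_hi_bp + 200, step=20.0, indep_prob=0.1))
        mu_o, sd_o = le.offset
        p_o = add_param(_Param(f"o:{le.individual}", mu_o, "rw" if sd_o > 0 else "fixed", step=max(sd_o, 1.0)))
        if sd_o > 0:
            add_factor(
                (lambda po=p_o, m=mu_o, s=sd_o: -0.5 * ((po.value - m) / s) ** 2),
                [p_o.name],
            )
        if le.age_at_death is not None:
            a_lo, a_hi = le.age_at_death
            add_param(
                _Param(
                    f"a:{le.individual}",
                    0.5 * (a_lo + a_hi),
                    "rw" if a_hi > a_lo else "fixed",
                    a_lo,
                    a_hi,
                    step=max((a_hi - a_lo) / 4.0, 0.5),
                )
            )
    for ev in model.extra_events:
        guesses = [init_event_guess(d) for d in model.dates if d.event == ev]
        guess = float(np.mean(guesses)) if guesses else 0.5 * (win_lo_bp + win_hi_bp)
        add_param(_Param(f"e:{ev}", guess, "rw", win_lo_bp - 200, win_hi_bp + 200, step=20.0, indep_prob=0.1))

    # charcoal outlier machinery
    has_outliers = any(d.charcoal_outlier for d in model.dates)
    if has_outliers:
        add_param(_Param("u", 1.0, "rw", 0.0, 3.0, step=0.4))

    # marine fractions + date likelihood factors
    def event_param_name(event: str) -> str:
        kind, _, ind = event.partition(":")
        if kind == "tissue":
            return f"t:{ind}"
        return f"e:{event}"

    for j, d in enumerate(model.dates):
        ev_name = event_param_name(d.event)
        if ev_name not in params:
            raise ModelValidationError(f"no latent parameter for event {d.event!r}")
        names = [ev_name]
        if d.histogram is not None:
            centers, weights = _hist_prior_support(d.histogram)
            m0 = float((centers * weights).sum())
            pm = add_param(_Param(f"m:{j}", m0, "hist"))
            pm.support = (centers, weights)  # type: ignore[attr-defined]
            names.append(pm.name)
            if dr.mode == "free":
                names.append("dR")
        shift_name = None
        if d.charcoal_outlier:
            pe = add_param(_Param(f"eps:{j}", 0.5, "rw", 1e-9, 10.0, step=0.3))
            names.extend([pe.name, "u"])
            shift_name = pe.name

        det = d.det
        hist = d.histogram

        def date_factor(
            det=det,
            hist=hist,
            ev=ev_name,
            mname=f"m:{j}",
            sname=shift_name,
        ) -> float:
            theta = params[ev].value
            if sname is not None:
                theta = theta + params[sname].value * 10.0 ** params["u"].value
            got = fast_terr.mu_sig(theta)
            if got is None:
                return -np.inf
            mu_t, s_t = got
            if hist is None:
                mu, var_c = mu_t, s_t * s_t
            else:
                got_m = fast_mar.mu_sig(theta)
                if got_m is None:
                    return -np.inf
                m = params[mname].value
                mu_m = got_m[0] + params["dR"].value
                s_m = got_m[1]
                mu = (1.0 - m) * mu_t + m * mu_m
                var_c = (1.0 - m) ** 2 * s_t * s_t + m * m * (s_m * s_m + fixed_dr_var)
            var = det.sigma * det.sigma + var_c
            d = det.age - mu
            return -0.5 * (d * d / var + math.log(var))

        add_factor(date_factor, names)

    # eps priors (Exp(1) truncated to (0, 10])
    for j, d in enumerate(model.dates):
        if d.charcoal_outlier:
            pe = params[f"eps:{j}"]
            add_factor((lambda pe=pe: -pe.value), [pe.name])

    # generational gaps: child_birth_AD - parent_birth_AD ~ N(mean, sd)
    # i.e. parent_birth_BP - child_birth_BP ~ N(mean, sd)
    def birth_terms(ind: str) -> tuple[str, str | None]:
        if ind not in by_ind:
            raise ModelValidationError(f"gap references unknown individual {ind!r}")
        le = by_ind[ind]
        oname = f"o:{ind}"
        return f"t:{ind}", oname if oname in params else None

    for g in model.gaps:
        tp, op = birth_terms(g.parent)
        tc, oc = birth_terms(g.child)
        names = [n for n in (tp, op, tc, oc) if n is not None and params[n].kind != "fixed"]

        def gap_factor(tp=tp, op=op, tc=tc, oc=oc, mean=g.mean, sd=g.sd) -> float:
            bp_parent = params[tp].value + (params[op].value if op else 0.0)
            bp_child = params[tc].value + (params[oc].value if oc else 0.0)
            return -0.5 * ((bp_parent - bp_child - mean) / sd) ** 2

        add_factor(gap_factor, names)

    # event resolver for phases/sequences
    def resolver(event: str) -> Callable[[], float]:
        kind, _, ind = event.partition(":")
        if f"e:{event}" in params:
            return lambda e=f"e:{event}": params[e].value
        if kind == "tissue":
            return lambda i=ind: params[f"t:{i}"].value
        if kind == "birth":
            return lambda i=ind: params[f"t:{i}"].value + params[f"o:{i}"].value
        if kind == "death":
            return lambda i=ind: (
                params[f"t:{i}"].value + params[f"o:{i}"].value - params[f"a:{i}"].value
            )
        if kind in ("start", "end"):
            return lambda e=f"b:{event}": params[e].value
        raise ModelValidationError(f"cannot resolve event {event!r}")

    def event_param_deps(event: str) -> list[str]:
        kind, _, ind = event.partition(":")
        if f"e:{event}" in params:
            return [f"e:{event}"]
        if kind in ("start", "end"):
            return [f"b:{event}"]
        deps = [f"t:{ind}"]
        if kind in ("birth", "death") and params[f"o:{ind}"].kind != "fixed":
            deps.append(f"o:{ind}")
        if kind == "death" and params[f"a:{ind}"].kind != "fixed":
            deps.append(f"a:{ind}")
        return deps

    def event_setter(event: str, target_bp: float) -> None:
        """Move the parameters behind an event so it sits at target_bp."""
        kind, _, ind = event.partition(":")
        if f"e:{event}" in params:
            params[f"e:{event}"].value = target_bp
            return
        t = params[f"t:{ind}"]
        o = params[f"o:{ind}"].value
        if kind == "tissue":
            t.value = target_bp
        elif kind == "birth":
            t.value = target_bp - o
        elif kind == "death":
            t.value = target_bp + params[f"a:{ind}"].value - o
        else:
            raise ModelValidationError(f"cannot initialize event {event!r}")

    # deterministic feasibility pass: walk each sequence from the oldest
    # group down, nudging members younger than everything older; done
    # before phase boundaries are initialized from member positions
    for sq in model.sequences:
        prev_min = np.inf
        for grp in sq.groups:
            vals = []
            for m in grp:
                v = resolver(m)()
                if v >= prev_min - 2.0:
                    event_setter(m, prev_min - 5.0)
                    v = resolver(m)()
                vals.append(v)
            prev_min = min(vals)

    # phases: members iid U(start, end); boundary prior 1/(start-end)
    for ph in model.phases:
        member_fns = [resolver(m) for m in ph.members]
        mvals = [fn() for fn in member_fns]
        b_start = add_param(
            _Param(f"b:{ph.start_event}", max(mvals) + 20.0, "rw", win_lo_bp, win_hi_bp + 400, step=20.0)
        )
        b_end = add_param(
            _Param(f"b:{ph.end_event}", min(mvals) - 20.0, "rw", win_lo_bp - 400, win_hi_bp, step=20.0)
        )
        names = {b_start.name, b_end.name}
        for m in ph.members:
            names.update(n for n in event_param_deps(m) if params[n].kind != "fixed")

        def phase_factor(fns=member_fns, bs=b_start, be=b_end, open_start=ph.open_start) -> float:
            start, end = bs.value, be.value  # cal BP: start older (larger)
            span = start - end
            if span <= 0:
                return -np.inf
            for fn in fns:
                v = fn()
                if (not open_start and v > start) or v < end:
                    return -np.inf
            return -(len(fns) + 1) * math.log(span)

        add_factor(phase_factor, sorted(names))

    # sequences: strict order between successive groups (BP decreasing)
    for sq in model.sequences:
        group_fns = [[resolver(m) for m in grp] for grp in sq.groups]
        names = set()
        for grp in sq.groups:
            for m in grp:
                names.update(n for n in event_param_deps(m) if params[n].kind != "fixed")

        def seq_factor(gfns=group_fns) -> float:
            prev_min = np.inf
            for fns in gfns:
                vals = [fn() for fn in fns]
                if max(vals) >= prev_min:
                    return -np.inf
                prev_min = min(vals)
            return 0.0

        add_factor(seq_factor, sorted(names))

    return params, factors


def _repair_initial_state(params: dict[str, _Param], factors, rng: np.random.Generator, tries: int = 4000) -> None:
    """Jitter parameters until no hard constraint factor is -inf."""

    def bad() -> bool:
        return any(not np.isfinite(f()) for f in factors)

    if not bad():
        return
    rw = [p for p in params.values() if p.kind == "rw"]
    for attempt in range(tries):
        scale = 1.0 + attempt / 50.0
        for p in rw:
            lo = p.lo if np.isfinite(p.lo) else p.value - 200
            hi = p.hi if np.isfinite(p.hi) else p.value + 200
            p.value = min(max(p.value + rng.normal(0, p.step * scale), lo), hi)
        if not bad():
            return
    raise McmcError("could not find a starting state satisfying the hard constraints")


def run_mcmc(
    model: ChronoModel,
    chains: int = 3,
    iterations: int = 6000,
    seed: int = 0,
    rhat_limit: float = 1.05,
    check_convergence: bool = True,
    rhat_params: Sequence[str] | None = None,
) -> PosteriorChains:
    """Sample the joint posterior.

    The first half of ``iterations`` is adaptive burn-in (per-parameter
    step tuning toward a 20-50% acceptance rate, frozen afterwards) and
    is discarded.  Fixed ``seed`` and configuration reproduce the draws
    bit-for-bit.  The Gelman-Rubin gate (max R-hat < ``rhat_limit``)
    is evaluated on ``rhat_params`` (default: every sampled parameter).
    """
    if chains < 3:
        raise ValueError("need at least 3 chains for the convergence diagnostic")
    burn = iterations // 2
    n_keep = iterations - burn
    root = np.random.default_rng(seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=chains)

    all_draws: dict[str, np.ndarray] | None = None
    acceptance: dict[str, float] = {}

    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        params, factors = _build_state(model, rng)
        _repair_initial_state(params, factors, rng)
        if all_draws is None:
            all_draws = {name: np.empty((chains, n_keep)) for name in params}
        sampled = [p for p in params.values() if p.kind != "fixed"]

        def local_logp(p: _Param) -> float:
            return sum(factors[i]() for i in p.factors)

        def total_logp() -> float:
            return sum(f() for f in factors)

        # block-move bookkeeping: the posterior's stiffest directions are
        # (a) translating the whole chronology along the calendar axis and
        # (b) moving Delta-R with compensating shifts of marine-dated events
        event_params = [
            p for p in sampled if p.name[:2] in ("t:", "e:", "b:")
        ]
        dr_param = params.get("dR")
        marine_links: dict[str, list[str]] = {}
        if dr_param is not None and dr_param.kind != "fixed":
            for j, d in enumerate(model.dates):
                if d.histogram is None:
                    continue
                kind, _, ind = d.event.partition(":")
                tname = f"t:{ind}" if kind == "tissue" else f"e:{d.event}"
                marine_links.setdefault(tname, []).append(f"m:{j}")
        # (c) gap-linked clusters (families) move rigidly: the gaps pin
        # their internal spacing, so the slow mode is absolute placement
        gap_adj: dict[str, set[str]] = {}
        for g in model.gaps:
            gap_adj.setdefault(g.parent, set()).add(g.child)
            gap_adj.setdefault(g.child, set()).add(g.parent)
        family_blocks: list[list[_Param]] = []
        seen_ids: set[str] = set()
        for start in sorted(gap_adj):
            if start in seen_ids:
                continue
            comp, stack = [], [start]
            while stack:
                node = stack.pop()
                if node in seen_ids:
                    continue
                seen_ids.add(node)
                comp.append(node)
                stack.extend(gap_adj.get(node, ()))
            block = [params[f"t:{i}"] for i in comp if params.get(f"t:{i}") is not None]
            if len(block) > 1:
                family_blocks.append(block)
        family_steps = [15.0] * len(family_blocks)

        translate_step = 12.0
        comp_step = 40.0
        block_acc = [0, 0] + [0] * len(family_blocks)
        block_tries = [0, 0] + [0] * len(family_blocks)

        def block_moves() -> None:
            nonlocal translate_step, comp_step
            # (a) rigid translation of every event and boundary
            block_tries[0] += 1
            delta = rng.normal(0.0, translate_step)
            cur = total_logp()
            for p in event_params:
                p.value += delta
            if math.log(rng.uniform()) < total_logp() - cur:
                block_acc[0] += 1
            else:
                for p in event_params:
                    p.value -= delta
            # (b) Delta-R with compensating marine-event shifts; the map
            # (dR, t_i) -> (dR + d, t_i + m_i d) is volume-preserving and
            # self-inverse under d -> -d, so the Hastings ratio is the
            # posterior ratio
            if dr_param is not None and dr_param.kind != "fixed" and marine_links:
                block_tries[1] += 1
                delta = rng.normal(0.0, comp_step)
                prop = dr_param.value + delta
                if dr_param.lo <= prop <= dr_param.hi:
                    cur = total_logp()
                    shifts = {}
                    for tname, mnames in marine_links.items():
                        mbar = float(np.mean([params[mn].value for mn in mnames]))
                        shifts[tname] = mbar * delta
                    dr_param.value = prop
                    for tname, s in shifts.items():
                        params[tname].value += s
                    if math.log(rng.uniform()) < total_logp() - cur:
                        block_acc[1] += 1
                    else:
                        dr_param.value = prop - delta
                        for tname, s in shifts.items():
                            params[tname].value -= s
            # (c) rigid family translations
            for k, block in enumerate(family_blocks):
                block_tries[2 + k] += 1
                delta = rng.normal(0.0, family_steps[k])
                cur = total_logp()
                for p in block:
                    p.value += delta
                if math.log(rng.uniform()) < total_logp() - cur:
                    block_acc[2 + k] += 1
                else:
                    for p in block:
                        p.value -= delta

        for it in range(iterations):
            for p in sampled:
                p.tries += 1
                old = p.value
                if p.kind == "hist":
                    centers, weights = p.support  # type: ignore[attr-defined]
                    # independence proposal from the prior: accept on the
                    # likelihood ratio alone
                    cur = local_logp(p)
                    p.value = float(centers[rng.choice(centers.size, p=weights)])
                    new = local_logp(p)
                    if math.log(rng.uniform()) >= new - cur:
                        p.value = old
                    else:
                        p.acc += 1
                    continue
                if p.indep_prob > 0.0 and rng.uniform() < p.indep_prob:
                    # uniform over [lo, hi]: constant proposal density,
                    # Hastings ratio reduces to the posterior ratio
                    prop = rng.uniform(p.lo, p.hi)
                else:
                    prop = old + rng.normal(0.0, p.step)
                if not p.lo <= prop <= p.hi:
                    continue
                cur = local_logp(p)
                p.value = prop
                new = local_logp(p)
                if math.log(rng.uniform()) < new - cur:
                    p.acc += 1
                else:
                    p.value = old
            block_moves()
            if it < burn and (it + 1) % 100 == 0:
                for k in range(len(block_tries)):
                    if block_tries[k] == 0:
                        continue
                    rate = block_acc[k] / block_tries[k]
                    scale = 0.75 if rate < 0.20 else (1.3 if rate > 0.50 else 1.0)
                    if k == 0:
                        translate_step *= scale
                    elif k == 1:
                        comp_step *= scale
                    else:
                        family_steps[k - 2] *= scale
                    block_acc[k] = 0
                    block_tries[k] = 0
                for p in sampled:
                    if p.kind != "rw":
                        p.acc = 0
                        p.tries = 0
                        continue
                    rate = p.acc / max(p.tries, 1)
                    if rate < 0.20:
                        p.step *= 0.75
                    elif rate > 0.50:
                        p.step *= 1.3
                    p.acc = 0
                    p.tries = 0
            if it >= burn:
                for name, p in params.items():
                    all_draws[name][c, it - burn] = p.value
        for p in sampled:
            if p.tries > 0 and p.acc == 0 and p.kind == "rw" and n_keep >= 500:
                raise McmcError(f"parameter {p.name} accepted no move after burn-in; tune steps")
        for p in sampled:
            acceptance[p.name] = p.acc / max(p.tries, 1)

    assert all_draws is not None
    watch = list(rhat_params) if rhat_params else [
        n for n, a in all_draws.items() if np.ptp(a) > 0
    ]
    rhat = {}
    for name in watch:
        arr = all_draws[name]
        if np.ptp(arr) == 0:
            rhat[name] = 1.0
            continue
        rhat[name] = float(az.rhat(az.convert_to_dataset(arr))["x"])
    chains_out = PosteriorChains(all_draws, rhat, acceptance, seed, model)
    if check_convergence:
        bad = {k: v for k, v in rhat.items() if not v < rhat_limit}
        if bad:
            raise McmcError(f"Gelman-Rubin gate failed (limit {rhat_limit}): {bad}", rhat)
    return chains_out


# ---------------------------------------------------------------------------
# agreement indices


def _standalone_density(
    model: ChronoModel, d: ModelDate, n_prior: int = 60, seed: int = 0
) -> CalendarDensity:
    """Stand-alone ("unmodeled") calibration of one determination,
    marginalized over the marine-fraction histogram prior and the
    Delta-R prior."""
    terr = model.curve_terrestrial
    if d.histogram is None:
        return calibrate_single(d.det, terr)
    rng = np.random.default_rng(seed)
    centers, weights = _hist_prior_support(d.histogram)
    dr = model.delta_r
    acc = None
    for _ in range(n_prior):
        m = float(centers[rng.choice(centers.size, p=weights)])
        if dr.mode == "free":
            delta = float(rng.uniform(dr.lower, dr.upper))
            off = ReservoirOffset("fixed", mean=delta, sd=0.0)
        else:
            off = ReservoirOffset("fixed", mean=dr.mean, sd=dr.sd)
        curve = mix_curves(terr, shift_marine(model.curve_marine, off), m)
        dens = calibrate_single(d.det, curve, window=(terr.span[0], terr.span[1]))
        grid = np.arange(terr.span[0], terr.span[1] + 1)
        w = np.zeros_like(grid, dtype=float)
        i0 = int(dens.grid[0] - grid[0])
        w[i0 : i0 + dens.grid.size] = dens.weights
        acc = w if acc is None else acc + w
    acc /= acc.sum()
    keep = acc > acc.max() * 1e-12
    idx = np.nonzero(keep)[0]
    sl = slice(idx[0], idx[-1] + 1)
    grid = np.arange(terr.span[0], terr.span[1] + 1)
    return CalendarDensity(grid[sl], acc[sl])


def agreement_index(p_modeled: np.ndarray, p_unmodeled: np.ndarray) -> float:
    """Overlap index between two probability mass functions on one grid:
    ``A = 100 * sum(p_mod * p_unmod) / sum(p_unmod^2)``.  Identical
    densities give 100; displacing the modeled density away from the
    stand-alone calibration monotonically lowers it."""
    p_modeled = np.asarray(p_modeled, dtype=float)
    p_unmodeled = np.asarray(p_unmodeled, dtype=float)
    if p_modeled.shape != p_unmodeled.shape:
        raise ValueError("densities must share one grid")
    den = float((p_unmodeled**2).sum())
    if den == 0:
        raise ValueError("unmodeled density is empty")
    return 100.0 * float((p_modeled * p_unmodeled).sum()) / den


def agreement_indices(
    chains: PosteriorChains, model: ChronoModel, seed: int = 0
) -> dict:
    """Per-date agreement ``A_i`` and the overall ``A_model``.

    ``A_i = 100 * int p_mod p_unmod / int p_unmod^2`` compares the
    date's modeled marginal posterior with its stand-alone calibration;
    ``A_model = 100 * prod(A_i / 100)^(1 / sqrt(n))``.  Dates with
    ``A_i < 60`` are flagged as being in tension with the model.
    """
    a_values: dict[str, float] = {}
    for j, d in enumerate(model.dates):
        unmod = _standalone_density(model, d, seed=seed)
        draws = chains.event_draws(d.event)
        if d.charcoal_outlier:
            draws = draws + chains.flat(f"eps:{j}") * 10.0 ** chains.flat("u")
        lo = unmod.grid[0]
        edges = np.concatenate([unmod.grid - 0.5, [unmod.grid[-1] + 0.5]])
        mod_w, _ = np.histogram(draws, bins=edges)
        inside = mod_w.sum()
        if inside == 0:
            a_values[d.det.lab_code] = 0.0
            continue
        mod_p = mod_w / draws.size
        a_values[d.det.lab_code] = agreement_index(mod_p, unmod.weights)
    n = len(a_values)
    logprod = sum(math.log(max(a, 1e-300) / 100.0) for a in a_values.values())
    a_model = 100.0 * math.exp(logprod / math.sqrt(n))
    return {
        "A_i": a_values,
        "A_model": a_model,
        "flagged": sorted(k for k, v in a_values.items() if v < 60.0),
    }
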