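"""Emission (and light parsing) of OxCal-dialect model code.

OxCal is the lingua franca for publishing chronological models, so the
package can export its models as OxCal scripts: calibration-curve
declarations, a reservoir-offset prior, per-individual mixed curves
whose marine proportion is a 100-bin probability array, and the
radiocarbon dates themselves, optionally wrapped in Sequence/Phase
blocks with boundaries.

The probability array ``P(-1,101,[...])`` carries exactly 102 values:
the 100 marine-percentage bin counts zero-padded on both ends, spanning
-1..101 so the histogram's outer bin edges are closed.  Only the
statement subset this package itself uses is supported; anything else
fails loudly.

Quotes are plain ASCII by default; ``typographic=True`` reproduces the
curly quotation marks some publications print.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chrono import ChronoModel, ModelDate, Phase, StratSequence
from .diet import DietHistogram

__all__ = [
    "OxCalEmissionError",
    "OxCalParseError",
    "emit_oxcal",
    "emit_flat",
    "parse_oxcal",
]


class OxCalEmissionError(ValueError):
    """The model cannot be expressed in the supported statement subset."""


class OxCalParseError(ValueError):
    """Unsupported or malformed OxCal statement."""


def _q(s: str, typographic: bool) -> str:
    return f"“{s}”" if typographic else f'"{s}"'


def _individual_of(date: ModelDate) -> str | None:
    kind, _, ind = date.event.partition(":")
    return ind if kind == "tissue" else None


def _p_array(hist: DietHistogram) -> str:
    vals = [0, *(int(c) for c in hist.counts), 0]
    return f"P(-1,101,[{','.join(str(v) for v in vals)}])"


def _date_statements(
    date: ModelDate,
    terr_name: str,
    dr_name: str,
    typographic: bool,
) -> list[str]:
    q = lambda s: _q(s, typographic)
    out = []
    if date.histogram is not None:
        ind = _individual_of(date) or date.det.lab_code
        out.append(
            f"Mix_Curves({q('Mix for ' + ind)}, {q(terr_name)}, {q(dr_name)}, "
            f"{_p_array(date.histogram)});"
        )
    out.append(f"R_Date({q(date.det.lab_code)},{date.det.age:g},{date.det.sigma:g});")
    return out


def emit_flat(
    dates: Sequence[ModelDate],
    delta_r_bounds: tuple[float, float] = (0.0, 100.0),
    terr_name: str = "SHCal20",
    terr_file: str = "SHCal20.14c",
    marine_name: str = "Marine20",
    marine_file: str = "Marine20.14c",
    dr_name: str = "LocalMarine",
    typographic: bool = False,
) -> str:
    """Emit the flat calibration script: curves, Delta-R, one
    Mix_Curves + R_Date pair per marine-diet date, a bare R_Date for
    terrestrial dates.

    Marine-diet dates must carry their histogram; a missing histogram is
    an :class:`OxCalEmissionError` (there is no defensible default)."""
    q = lambda s: _q(s, typographic)
    lo, hi = delta_r_bounds
    lines = [
        f"Curve({q(terr_name)},{q(terr_file)});",
        f"Curve({q(marine_name)},{q(marine_file)});",
        f"Delta_R({q(dr_name)},U({lo:g},{hi:g}));",
    ]
    for d in dates:
        lines.extend(_date_statements(d, terr_name, dr_name, typographic))
    return "\n".join(lines) + "\n"


def emit_oxcal(
    model: ChronoModel,
    histograms: dict[str, DietHistogram] | None = None,
    marine_individuals: set[str] | None = None,
    delta_r_bounds: tuple[float, float] | None = None,
    typographic: bool = False,
) -> str:
    """Emit a full model as OxCal code.

    ``histograms`` may supply (or override) marine-diet histograms by
    individual id.  ``marine_individuals`` declares who ate marine
    protein; every date on such an individual must end up with a
    histogram, otherwise :class:`OxCalEmissionError` is raised (there
    is no defensible default mixture).  Dates are wrapped in the
    model's Phase and Sequence structure; boundaries bracket each
    phase.  Delta-R bounds default to the model's free-mode prior.
    """
    histograms = histograms or {}
    dates = []
    for d in model.dates:
        ind = _individual_of(d)
        hist = histograms.get(ind) if ind else None
        hist = hist if hist is not None else d.histogram
        if hist is None and marine_individuals and ind in marine_individuals:
            raise OxCalEmissionError(
                f"marine-diet individual {ind} (date {d.det.lab_code}) has no "
                f"marine histogram"
            )
        dates.append(ModelDate(d.det, d.event, hist, d.charcoal_outlier))
    if delta_r_bounds is None:
        dr = model.delta_r
        delta_r_bounds = (dr.lower, dr.upper) if dr.mode == "free" else (dr.mean, dr.mean)
    q = lambda s: _q(s, typographic)
    lines = [
        f"Curve({q(model.curve_terrestrial.name)},{q(model.curve_terrestrial.name + '.14c')});",
        f"Curve({q(model.curve_marine.name)},{q(model.curve_marine.name + '.14c')});",
        f"Delta_R({q('LocalMarine')},U({delta_r_bounds[0]:g},{delta_r_bounds[1]:g}));",
    ]
    if any(d.charcoal_outlier for d in dates):
        lines.append(
            f'Outlier_Model({q("Charcoal")},Exp(1,-10,0),U(0,3),{q("t")});'
        )

    by_event: dict[str, list[ModelDate]] = {}
    for d in dates:
        by_event.setdefault(d.event, []).append(d)
    emitted: set[str] = set()

    def date_block(d: ModelDate, indent: str) -> list[str]:
        stmts = _date_statements(d, model.curve_terrestrial.name, "LocalMarine", typographic)
        if d.charcoal_outlier:
            head = stmts[-1][:-1]  # strip ';'
            stmts[-1] = f"{head}{{Outlier({q('Charcoal')},1);}};"
        emitted.add(d.det.lab_code)
        return [indent + s for s in stmts]

    def events_block(events: Iterable[str], indent: str) -> list[str]:
        out = []
        for ev in events:
            for d in by_event.get(ev, []):
                out.extend(date_block(d, indent))
        return out

    for sq in model.sequences:
        lines.append(f"Sequence({q(sq.name)})")
        lines.append("{")
        lines.append(f" Boundary({q('start ' + sq.name)});")
        for i, grp in enumerate(sq.groups):
            lines.append(f" Phase({q(f'{sq.name} {i}')})")
            lines.append(" {")
            lines.extend(events_block(grp, "  "))
            lines.append(" };")
        lines.append(f" Boundary({q('end ' + sq.name)});")
        lines.append("};")
    for ph in model.phases:
        lines.append(f"Sequence({q(ph.name)})")
        lines.append("{")
        if not ph.open_start:
            lines.append(f" Boundary({q('start ' + ph.name)});")
        lines.append(f" Phase({q(ph.name)})")
        lines.append(" {")
        lines.extend(events_block(ph.members, "  "))
        lines.append(" };")
        lines.append(f" Boundary({q('end ' + ph.name)});")
        lines.append("};")
    for d in dates:
        if d.det.lab_code not in emitted:
            lines.extend(date_block(d, ""))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# light parsing (round-trip support for the flat statement subset)

_QUOTE_MAP = str.maketrans({"“": '"', "”": '"', "’": "'", "−": "-"})

_CURVE_RE = re.compile(r'^Curve\("([^"]*)","([^"]*)"\);$')
_DR_RE = re.compile(r'^Delta_R\("([^"]*)",U\(([-\d.]+),([-\d.]+)\)\);$')
_MIX_RE = re.compile(
    r'^Mix_Curves\("Mix for ([^"]*)", "([^"]*)", "([^"]*)", P\(-1,101,\[([\d,]+)\]\)\);$'
)
_RDATE_RE = re.compile(r'^R_Date\("([^"]*)",([-\d.]+),([-\d.]+)\);$')


def parse_oxcal(text: str) -> list[tuple]:
    """Parse the flat statement subset back into structured tuples.

    Curly quotes and the typographic minus are normalized first, so a
    script emitted with ``typographic=True`` parses identically.
    Returns tuples tagged ``("curve", name, file)``,
    ``("delta_r", name, lo, hi)``, ``("mix", individual, terr, dr,
    counts)`` and ``("r_date", label, age, sigma)``.  Raises
    :class:`OxCalParseError` on anything else.
    """
    out: list[tuple] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.translate(_QUOTE_MAP).strip()
        if not line:
            continue
        if m := _CURVE_RE.match(line):
            out.append(("curve", m.group(1), m.group(2)))
        elif m := _DR_RE.match(line):
            out.append(("delta_r", m.group(1), float(m.group(2)), float(m.group(3))))
        elif m := _MIX_RE.match(line):
            counts = [int(v) for v in m.group(4).split(",")]
            if len(counts) != 102:
                raise OxCalParseError(
                    f"line {lineno}: P array has {len(counts)} values, expected 102"
                )
            out.append(("mix", m.group(1), m.group(2), m.group(3), counts))
        elif m := _RDATE_RE.match(line):
            out.append(("r_date", m.group(1), float(m.group(2)), float(m.group(3))))
        else:
            raise OxCalParseError(f"line {lineno}: unsupported statement {raw!r}")
    return out
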