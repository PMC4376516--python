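"""Date dialect handling shared across the package.

Source collections deliver dates in their own textual dialects; the hub
normalises them to :class:`datetime.date` at load, and standardised research
outputs render them as ``YYYYMMDD``.  All parsing is strict: "31/02/2010" is an
invalid calendar date, not a coercible one.
"""

from __future__ import annotations

import datetime as _dt

from .errors import SchemaError

# dialect name -> strptime/strftime pattern
DIALECTS: dict[str, str] = {
    "DD/MM/YYYY": "%d/%m/%Y",
    "YYYYMMDD": "%Y%m%d",
    "YYYY-MM-DD": "%Y-%m-%d",
}

#: dialect used for researcher-facing standardised output
CANONICAL_DIALECT = "YYYYMMDD"


def _pattern(dialect: str) -> str:
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise SchemaError(
            f"unknown date dialect {dialect!r}; supported: {sorted(DIALECTS)}"
        ) from None


def render_date(value: _dt.date, dialect: str) -> str:
    return value.strftime(_pattern(dialect))


def parse_date(text: str, dialect: str) -> _dt.date:
    """Parse *text* in the given dialect; raises ValueError on bad dates."""
    pattern = _pattern(dialect)
    parsed = _dt.datetime.strptime(text.strip(), pattern).date()
    # strptime tolerates e.g. "1/2/2010" for "%d/%m/%Y"; round-trip to enforce
    # the dialect's fixed width.
    if parsed.strftime(pattern) != text.strip():
        raise ValueError(f"{text!r} is not a valid {dialect} date")
    return parsed


def parse_date_any(text: str, dialects: tuple[str, ...] | None = None) -> _dt.date:
    """Parse *text* trying the canonical dialects in a fixed order."""
    tried = dialects or (CANONICAL_DIALECT, "YYYY-MM-DD", "DD/MM/YYYY")
    for d in tried:
        try:
            return parse_date(text, d)
        except ValueError:
            continue
    raise ValueError(f"{text!r} matches no date dialect in {tried}")
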