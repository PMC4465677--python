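"""PRESENCE-style PAO text files.

A deliberately small, line-oriented dialect of the PRESENCE data-file
family, sufficient to carry a :class:`~occucam.detection_data.DetectionHistory`
together with per-site covariates.  The grammar (one directive per line,
whitespace-delimited, ``;`` starts a comment)::

    ; occucam PAO 1
    title <free text>
    kind <binary|multistate>
    sites <n_sites>
    occasions <n_weeks>
    seasons <label>:<year>:<n_weeks>[:<iso start date>] , ...
    history
    <site_id> <code> ... <code>          ; one row per site, '-' = missing
    effort
    <site_id> <days> ... <days>          ; active camera days, 0-7
    sitecov <name>                        ; zero or more blocks
    <site_id> <value>
    end

Missing observations are written as ``-`` and must coincide with zero
effort.  Output is deterministic: writing the same objects twice yields
identical bytes, and ``read_pao(write_pao(h))`` restores observations,
effort, layout and covariates exactly (floats are serialised with
``repr`` so the round trip is bit-exact).
"""

from __future__ import annotations

from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from occucam.detection_data import MISSING, DetectionHistory, Season, SeasonLayout
from occucam.habitat_covariates import SiteCovariates

_MAGIC = "; occucam PAO 1"


class PaoParseError(ValueError):
    """Raised with the offending line number on malformed input."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _fmt_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_pao(
    history: DetectionHistory,
    covariates: SiteCovariates | None = None,
    path: str | Path = None,
    title: str = "occucam detection history",
) -> str:
    """Serialise a detection history (and optional site covariates).

    Returns the file text; writes it to ``path`` when given.
    """
    for sid in history.site_ids:
        if any(c.isspace() for c in sid):
            raise ValueError(f"site id {sid!r} contains whitespace")
    lines = [_MAGIC, f"title {title}", f"kind {history.kind}",
             f"sites {history.n_sites}", f"occasions {history.layout.total_weeks}"]
    season_specs = []
    for s in history.layout.seasons:
        spec = f"{s.label}:{s.year}:{s.n_weeks}"
        if s.start is not None:
            spec += f":{s.start.isoformat()}"
        season_specs.append(spec)
    lines.append("seasons " + ",".join(season_specs))
    lines.append("history")
    for i, sid in enumerate(history.site_ids):
        cells = ["-" if c == MISSING else str(c) for c in history.observations[i]]
        lines.append(sid + " " + " ".join(cells))
    lines.append("effort")
    for i, sid in enumerate(history.site_ids):
        lines.append(sid + " " + " ".join(str(e) for e in history.effort[i]))
    if covariates is not None:
        frame = covariates.data.loc[history.site_ids]
        for name in frame.columns:
            lines.append(f"sitecov {name}")
            for sid in history.site_ids:
                lines.append(f"{sid} {_fmt_value(frame.at[sid, name])}")
    lines.append("end")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _parse_seasons(lineno: int, spec: str) -> SeasonLayout:
    seasons = []
    first = 0
    for part in spec.split(","):
        bits = part.split(":")
        if len(bits) not in (3, 4):
            raise PaoParseError(lineno, f"bad season spec {part!r}")
        label, year, n_weeks = bits[0], bits[1], bits[2]
        start = date.fromisoformat(bits[3]) if len(bits) == 4 else None
        try:
            seasons.append(Season(label, int(year), first, int(n_weeks), start))
        except ValueError as exc:
            raise PaoParseError(lineno, str(exc)) from exc
        first += int(n_weeks)
    return SeasonLayout(tuple(seasons))


def _parse_matrix_row(lineno: int, line: str, n_occ: int, allow_missing: bool):
    parts = line.split()
    if len(parts) != n_occ + 1:
        raise PaoParseError(
            lineno, f"expected site id + {n_occ} cells, found {len(parts) - 1}"
        )
    sid, cells = parts[0], parts[1:]
    row = np.empty(n_occ, dtype=int)
    for j, cell in enumerate(cells):
        if cell == "-":
            if not allow_missing:
                raise PaoParseError(lineno, "'-' not allowed in effort block")
            row[j] = MISSING
        else:
            try:
                row[j] = int(cell)
            except ValueError:
                raise PaoParseError(lineno, f"non-numeric cell {cell!r}") from None
    return sid, row


def read_pao(path: str | Path) -> tuple[DetectionHistory, SiteCovariates | None]:
    """Parse a PAO file written by :func:`write_pao` (or by hand)."""
    raw = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    layout = None
    i = 0
    n = len(raw)

    def err(msg: str) -> PaoParseError:
        return PaoParseError(i + 1, msg)

    # header
    while i < n:
        line = raw[i].strip()
        if not line or line.startswith(";"):
            i += 1
            continue
        key, _, rest = line.partition(" ")
        if key == "history":
            break
        if key == "seasons":
            layout = _parse_seasons(i + 1, rest.strip())
        elif key in ("title", "kind", "sites", "occasions"):
            header[key] = rest.strip()
        else:
            raise err(f"unknown directive {key!r}")
        i += 1
    for req in ("kind", "sites", "occasions"):
        if req not in header:
            raise err(f"missing {req!r} declaration")
    if layout is None:
        raise err("missing 'seasons' declaration")
    try:
        n_sites, n_occ = int(header["sites"]), int(header["occasions"])
    except ValueError:
        raise err("sites/occasions must be integers") from None
    if layout.total_weeks != n_occ:
        raise err(
            f"seasons declare {layout.total_weeks} weeks but occasions = {n_occ}"
        )
    if i >= n:
        raise err("missing 'history' block")

    def read_block(allow_missing: bool):
        nonlocal i
        i += 1
        sids, rows = [], []
        while len(rows) < n_sites:
            if i >= n:
                raise err("unexpected end of file inside matrix block")
            line = raw[i].strip()
            if not line or line.startswith(";"):
                i += 1
                continue
            sid, row = _parse_matrix_row(i + 1, line, n_occ, allow_missing)
            sids.append(sid)
            rows.append(row)
            i += 1
        return sids, np.vstack(rows)

    site_ids, obs = read_block(allow_missing=True)
    while i < n and (not raw[i].strip() or raw[i].strip().startswith(";")):
        i += 1
    if i >= n or raw[i].strip() != "effort":
        raise err("expected 'effort' block after history")
    effort_ids, effort = read_block(allow_missing=False)
    if effort_ids != site_ids:
        raise err("effort block site ids differ from history block")

    cov_blocks: dict[str, list] = {}
    while i < n:
        line = raw[i].strip()
        if not line or line.startswith(";"):
            i += 1
            continue
        if line == "end":
            break
        key, _, name = line.partition(" ")
        if key != "sitecov" or not name.strip():
            raise err(f"expected 'sitecov <name>' or 'end', got {line!r}")
        name = name.strip()
        i += 1
        values = []
        got = 0
        while got < n_sites:
            if i >= n:
                raise err(f"unexpected end of file in sitecov {name!r}")
            line = raw[i].strip()
            if not line or line.startswith(";"):
                i += 1
                continue
            parts = line.split()
            if len(parts) != 2:
                raise err(f"sitecov rows are '<site_id> <value>', got {line!r}")
            sid, val = parts
            if sid != site_ids[got]:
                raise err(f"sitecov {name!r}: expected site {site_ids[got]!r}")
            # preserve the written token type so re-writing is byte-stable
            try:
                values.append(int(val))
            except ValueError:
                try:
                    values.append(float(val))
                except ValueError:
                    values.append(val)
            got += 1
            i += 1
        cov_blocks[name] = values

    history = DetectionHistory(
        site_ids=site_ids,
        layout=layout,
        observations=obs,
        effort=effort,
        kind=header["kind"],
    )
    covariates = None
    if cov_blocks:
        frame = pd.DataFrame(cov_blocks, index=pd.Index(site_ids, name="site_id"))
        covariates = SiteCovariates(frame)
    return history, covariates
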