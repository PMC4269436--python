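"""Reading and writing delimited game-result files.

Real-league result files come in many layouts, so the reader is driven by a
:class:`GameFileDialect` mapping the five required roles (round, the two
teams, the two scores) onto columns, by header name or by position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .network import GameRecord, ValidationError


class GameFileError(ValidationError):
    """A game file line failed to parse; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


ROLES = ("round", "team_a", "score_a", "team_b", "score_b")


@dataclass(frozen=True)
class GameFileDialect:
    """Layout of a delimited game file.

    ``columns`` maps each role to a header name (when ``header``) or a
    0-based column position (when not). All five roles must map to distinct
    columns. Team IDs are opaque: any characters are preserved verbatim.
    """

    delimiter: str = ","
    columns: dict = field(
        default_factory=lambda: {r: r for r in ROLES}
    )
    header: bool = True
    encoding: str = "utf-8"

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.columns]
        if missing:
            raise ValidationError(f"dialect missing roles: {missing}")
        if len(set(self.columns[r] for r in ROLES)) != len(ROLES):
            raise ValidationError("dialect maps two roles to the same column")


DIALECTS: dict[str, GameFileDialect] = {
    "default": GameFileDialect(),
    # headerless whitespace-separated: round teamA scoreA teamB scoreB
    "plain": GameFileDialect(
        delimiter=r"\s+",
        columns={r: i for i, r in enumerate(ROLES)},
        header=False,
    ),
}


def parse_games(
    path: str | Path | io.TextIOBase, dialect: GameFileDialect | str = "default"
) -> list[GameRecord]:
    """Parse a delimited game file into validated records.

    Malformed lines raise :class:`GameFileError` citing the 1-based file
    line number and the offending field.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        header=0 if dialect.header else None,
        encoding=dialect.encoding,
        dtype=str,
        engine="python",
        skip_blank_lines=False,
    )
    first_line = 2 if dialect.header else 1
    for role in ROLES:
        col = dialect.columns[role]
        if (dialect.header and col not in df.columns) or (
            not dialect.header and col >= df.shape[1]
        ):
            raise GameFileError(f"column for {role!r} ({col!r}) not found in file")
    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = first_line + pos
        if row.isna().all():
            continue  # blank line
        vals = {}
        for role in ROLES:
            raw = row[dialect.columns[role]]
            if pd.isna(raw):
                raise GameFileError(f"missing field {role!r}", line)
            vals[role] = str(raw).strip()
        try:
            rnd = int(vals["round"])
            sa = float(vals["score_a"])
            sb = float(vals["score_b"])
        except ValueError as exc:
            raise GameFileError(f"non-numeric field: {exc}", line) from None
        try:
            records.append(
                GameRecord(rnd, vals["team_a"], sa, vals["team_b"], sb)
            )
        except ValidationError as exc:
            raise GameFileError(str(exc), line) from None
    return records


def write_games(
    path: str | Path | io.TextIOBase,
    games: Sequence[GameRecord],
    dialect: GameFileDialect | str = "default",
) -> None:
    """Write records in a layout :func:`parse_games` reads back verbatim."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    sep = " " if dialect.delimiter == r"\s+" else dialect.delimiter

    def fmt(s: float) -> str:
        return str(int(s)) if float(s) == int(s) else repr(float(s))

    if dialect.header:
        order = list(ROLES)  # header maps by name, so canonical order is fine
    else:
        order = sorted(ROLES, key=lambda r: int(dialect.columns[r]))
    lines = []
    if dialect.header:
        lines.append(sep.join(str(dialect.columns[r]) for r in order))
    for g in games:
        vals = {
            "round": str(g.round),
            "team_a": g.team_a,
            "score_a": fmt(g.score_a),
            "team_b": g.team_b,
            "score_b": fmt(g.score_b),
        }
        lines.append(sep.join(vals[r] for r in order))
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text, encoding=dialect.encoding)
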