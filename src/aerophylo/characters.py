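"""Discretization of derivative estimates into a taxa x 20 character matrix.

Stability characters take three unordered states -- stable, marginal,
unstable -- decided by whether the 75% confidence interval of the slope
includes zero (marginal) and otherwise by the sign of the slope.  Control
characters are binary: a movement is effective when the magnitude of
dC/ddelta exceeds a threshold (default 0.09 per radian, one tenth of the
restoring slope of a weathervane reference, equivalently the moment needed
to displace the center of pressure by about 10% of body length); the
absolute value is used because sign encodes direction, not capability.

The matrix is written as a Mesquite-compatible NEXUS STANDARD block
(symbols 012 for stable/marginal/unstable, 01 for ineffective/effective,
missing '?') alongside plain CSV exports of both the discretized and the
continuous (raw slope) matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .synthetic import CHARACTER_LABELS

__all__ = [
    "CharacterMatrix",
    "code_stability",
    "code_control",
    "build_matrix",
    "EFFECTIVENESS_THRESHOLD",
    "STABILITY_SYMBOLS",
    "CONTROL_SYMBOLS",
]

EFFECTIVENESS_THRESHOLD = 0.09  # rad^-1

STABILITY_SYMBOLS = {"stable": "0", "marginal": "1", "unstable": "2"}
CONTROL_SYMBOLS = {"ineffective": "0", "effective": "1"}
_STABILITY_STATES = {v: k for k, v in STABILITY_SYMBOLS.items()}
_CONTROL_STATES = {v: k for k, v in CONTROL_SYMBOLS.items()}


def character_kind(label: str) -> str:
    """'stability' or 'control', inferred from the canonical label prefix."""
    if label.startswith("stab_"):
        return "stability"
    if label.startswith("ctrl_"):
        return "control"
    raise ValueError(f"cannot infer character kind from label {label!r}")


def code_stability(est) -> str:
    """stable / marginal / unstable from a slope and its interval ('?' if absent)."""
    if est is None:
        return "?"
    if est.ci_low <= 0.0 <= est.ci_high:
        return "marginal"
    return "stable" if est.slope < 0 else "unstable"


def code_control(est, threshold: float = EFFECTIVENESS_THRESHOLD) -> str:
    """effective iff |dC/ddelta| strictly exceeds the threshold ('?' if absent)."""
    if est is None:
        return "?"
    return "effective" if abs(est.slope) > threshold else "ineffective"


@dataclass
class CharacterMatrix:
    """Taxa x characters table of discrete states.

    ``states`` is a DataFrame indexed by taxon with character-label columns;
    cells hold state names (or ``"?"``).
    """

    states: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def taxa(self):
        return list(self.states.index)

    @property
    def characters(self):
        return list(self.states.columns)

    def symbol(self, taxon: str, label: str) -> str:
        state = self.states.at[taxon, label]
        if state == "?":
            return "?"
        table = STABILITY_SYMBOLS if character_kind(label) == "stability" else CONTROL_SYMBOLS
        return table[state]

    def to_csv(self, path) -> None:
        self.states.to_csv(path, index_label="taxon")

    @classmethod
    def from_csv(cls, path) -> "CharacterMatrix":
        return cls(pd.read_csv(path, index_col="taxon"))

    def to_nexus(self, path) -> None:
        """Write a TAXA + CHARACTERS NEXUS file (STANDARD datatype)."""
        taxa = self.taxa
        chars = self.characters
        lines = ["#NEXUS", "", "BEGIN TAXA;", f"    DIMENSIONS NTAX={len(taxa)};"]
        lines.append("    TAXLABELS " + " ".join(_sanitize(t) for t in taxa) + ";")
        lines += ["END;", "", "BEGIN CHARACTERS;", f"    DIMENSIONS NCHAR={len(chars)};",
                  '    FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=?;']
        if chars:
            statelabels = []
            for i, label in enumerate(chars, start=1):
                names = (
                    ("stable", "marginal", "unstable")
                    if character_kind(label) == "stability"
                    else ("ineffective", "effective")
                )
                statelabels.append(f"{i} {_sanitize(label)} / " + " ".join(names))
            lines.append("    CHARSTATELABELS " + ", ".join(statelabels) + ";")
        lines.append("    MATRIX")
        width = max((len(_sanitize(t)) for t in taxa), default=0) + 2
        for taxon in taxa:
            row = "".join(self.symbol(taxon, c) for c in chars)
            lines.append(f"    {_sanitize(taxon):<{width}}{row}")
        lines += ["    ;", "END;", ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))

    @classmethod
    def from_nexus(cls, path) -> "CharacterMatrix":
        """Read a STANDARD matrix back, decoding states via CHARSTATELABELS.

        dendropy parses the block; character labels (dropped by dendropy)
        are recovered from the CHARSTATELABELS statement when present, else
        generic ``char_N`` labels and raw symbols are used.
        """
        matrix = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
        with open(path) as fh:
            labels = _charstatelabels(fh.read())
        ncol = max(len(matrix[t]) for t in matrix) if len(matrix) else 0
        if labels is None:
            labels = [f"char_{i + 1}" for i in range(ncol)]
        rows = {}
        for taxon in matrix:
            symbols = [str(cell) for cell in matrix[taxon]]
            rows[taxon.label] = [
                _decode(sym, label) for sym, label in zip(symbols, labels)
            ]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
        return cls(df)


def _sanitize(label: str) -> str:
    return re.sub(r"[\s;,()\[\]]+", "_", str(label))


def _decode(symbol: str, label: str) -> str:
    if symbol == "?":
        return "?"
    try:
        kind = character_kind(label)
    except ValueError:
        return symbol
    table = _STABILITY_STATES if kind == "stability" else _CONTROL_STATES
    return table.get(symbol, symbol)


def _charstatelabels(text: str):
    m = re.search(r"CHARSTATELABELS\s+(.*?);", text, flags=re.IGNORECASE | re.DOTALL)
    if not m:
        return None
    labels = []
    for entry in m.group(1).split(","):
        parts = entry.split("/")[0].split()
        if len(parts) >= 2:
            labels.append(parts[1])
    return labels or None


def build_matrix(
    estimates: dict,
    threshold: float = EFFECTIVENESS_THRESHOLD,
    characters=CHARACTER_LABELS,
):
    """Assemble the discretized and continuous matrices from estimates.

    ``estimates`` maps taxon -> {character label -> DerivativeEstimate or
    None} (the output of ``estimate_all``).  Returns ``(CharacterMatrix,
    continuous)`` where ``continuous`` holds the raw slopes (NaN when
    missing).  Duplicate (taxon, character) assignments raise.
    """
    if isinstance(estimates, pd.DataFrame):
        dup = estimates.duplicated(subset=["taxon", "character"])
        if dup.any():
            pairs = estimates.loc[dup, ["taxon", "character"]].values.tolist()
            raise ValueError(f"duplicate (taxon, character) estimates: {pairs}")
        from .derivatives import frame_to_estimates

        estimates = frame_to_estimates(estimates)
    characters = list(characters)
    rows, slope_rows = {}, {}
    for taxon, per_char in estimates.items():
        if taxon in rows:
            raise ValueError(f"duplicate taxon {taxon!r}")
        states, slopes = {}, {}
        for label in characters:
            est = per_char.get(label)
            if character_kind(label) == "stability":
                states[label] = code_stability(est)
            else:
                states[label] = code_control(est, threshold)
            slopes[label] = est.slope if est is not None else float("nan")
        rows[taxon] = states
        slope_rows[taxon] = slopes
    taxa = sorted(rows)
    discrete = pd.DataFrame([rows[t] for t in taxa], index=taxa, columns=characters)
    continuous = pd.DataFrame([slope_rows[t] for t in taxa], index=taxa, columns=characters)
    discrete.index.name = continuous.index.name = "taxon"
    return CharacterMatrix(discrete), continuous
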