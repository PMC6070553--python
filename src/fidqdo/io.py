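"""File formats, run configuration and the CBS extrapolation helper.

User-facing files use angstrom and elementary charges:

* geometry — standard XYZ (count line, comment line, ``El x y z`` rows);
* charges — whitespace-delimited rows ``x y z q`` with ``#`` comments;
* parameters — per-element table, see :func:`fidqdo.qdo.load_parameter_table`;
* run configuration — a YAML mapping, see :class:`RunConfig`.

Fragment assignment uses 1-based inclusive atom index ranges ("1-5,7"),
matching the convention of most chemistry file tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .units import InvalidParameterError

logger = logging.getLogger("fidqdo")

__all__ = [
    "ParseError",
    "read_xyz",
    "read_charges",
    "parse_index_ranges",
    "cbs_extrapolate",
    "RunConfig",
]

#: recognized element symbols (H..Lr)
ELEMENTS = set(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr".split()
)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_xyz(path: str | Path) -> list[tuple[str, tuple[float, float, float]]]:
    """Parse a standard XYZ file (coordinates in angstrom).

    Line 1: atom count; line 2: comment; then one ``El x y z`` row per
    atom.  Extra per-line columns are ignored with a warning.  Element
    symbols are normalized to title case.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}, line 1: expected an atom count, got {lines[0]!r}") from None
    atoms = []
    warned_extra = False
    for i in range(count):
        lineno = i + 3
        if len(lines) < lineno or not lines[lineno - 1].strip():
            raise ParseError(
                f"{path}, line {lineno}: expected atom record {i + 1} of {count}, "
                "but the file ended"
            )
        parts = lines[lineno - 1].split()
        if len(parts) < 4:
            raise ParseError(
                f"{path}, line {lineno}: expected 'element x y z', got {lines[lineno - 1]!r}"
            )
        el = parts[0].capitalize()
        if el not in ELEMENTS:
            raise ParseError(f"{path}, line {lineno}: unknown element symbol {parts[0]!r}")
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise ParseError(
                f"{path}, line {lineno}: non-numeric coordinate in {lines[lineno - 1]!r}"
            ) from None
        if len(parts) > 4 and not warned_extra:
            logger.warning("%s, line %d: ignoring extra columns beyond x y z", path, lineno)
            warned_extra = True
        atoms.append((el, (x, y, z)))
    return atoms


def read_charges(path: str | Path) -> list[tuple[tuple[float, float, float], float]]:
    """Parse external point charges: rows ``x y z q`` (angstrom, e).

    ``#`` comments and blank lines are skipped; a zero charge magnitude is
    rejected.  An empty file yields an empty list (plain dispersion run)
    with a warning.
    """
    path = Path(path)
    charges = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{path}, line {lineno}: expected 'x y z q', got {raw!r}")
        try:
            x, y, z, q = (float(p) for p in parts)
        except ValueError:
            raise ParseError(f"{path}, line {lineno}: non-numeric field in {raw!r}") from None
        if q == 0.0:
            raise ParseError(f"{path}, line {lineno}: external charge magnitude must be nonzero")
        charges.append(((x, y, z), q))
    if not charges:
        logger.warning("%s: no external charges; this is a plain dispersion run", path)
    return charges


def parse_index_ranges(spec: str, n_atoms: int) -> list[int]:
    """Parse "1-5,8" style 1-based inclusive atom ranges into 0-based indices."""
    out: list[int] = []
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            a, _, b = chunk.partition("-")
            try:
                lo, hi = int(a), int(b)
            except ValueError:
                raise ParseError(f"bad index range {chunk!r}") from None
        else:
            try:
                lo = hi = int(chunk)
            except ValueError:
                raise ParseError(f"bad atom index {chunk!r}") from None
        if lo < 1 or hi > n_atoms or lo > hi:
            raise ParseError(
                f"index range {chunk!r} outside 1..{n_atoms} (indices are 1-based inclusive)"
            )
        out.extend(range(lo - 1, hi))
    if len(set(out)) != len(out):
        raise ParseError(f"fragment ranges overlap in {spec!r}")
    return out


def cbs_extrapolate(E1: float, n1: int, E2: float, n2: int) -> float:
    """Two-point cubic complete-basis-set extrapolation.

    E(inf) = (E(n1) n1^3 - E(n2) n2^3) / (n1^3 - n2^3); exact for energies
    following E(n) = E(inf) + b / n^3.  Provided for pre-processing
    user-supplied correlated reference energies before comparison.
    """
    if n1 == n2:
        raise InvalidParameterError("CBS extrapolation needs two distinct cardinal numbers")
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("cardinal numbers must be >= 2")
    return (E1 * n1**3 - E2 * n2**3) / (n1**3 - n2**3)


@dataclass
class RunConfig:
    """Configuration of one ``fid compute`` run (paths and options)."""

    geometry: str
    fragment_a: str
    fragment_b: str
    charges: str | None = None
    parameters: str | None = None
    hirshfeld_ratios: list[float] = field(default_factory=list)
    units: str = "meV"
    include_intra: bool = False
    output: str | None = None
    seed: int = 0
    oracle_nmax: int = 8
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        missing = {"geometry", "fragment_a", "fragment_b"} - set(data)
        if missing:
            raise ParseError(f"{path}: missing required config keys {sorted(missing)}")
        return cls(**data)
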