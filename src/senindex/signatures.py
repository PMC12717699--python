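"""Directional gene signatures and auxiliary gene lists.

A directional signature splits its genes into an up-regulated set (expected
elevated in the target state, e.g. senescence) and a down-regulated set
(expected depleted).  Signatures are loaded from data files -- either a
two-line GMT pair named ``<NAME>_UP`` / ``<NAME>_DN``, or a two-column
``symbol,direction`` table -- and validated structurally: the two directions
must be disjoint and at least one must be non-empty.

Gene symbols are upper-cased by default so that human (``CDKN1A``) and mouse
(``Cdkn1a``) capitalizations match the same signature entry; pass
``case_sensitive=True`` to disable this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    """Raised for malformed signature or gene-list files."""


def _normalize(symbols: Iterable[str], case_sensitive: bool) -> list[str]:
    """Strip, optionally upper-case, and deduplicate preserving order."""
    seen: dict[str, None] = {}
    n_dup = 0
    for s in symbols:
        s = s.strip()
        if not s:
            continue
        if not case_sensitive:
            s = s.upper()
        if s in seen:
            n_dup += 1
        else:
            seen[s] = None
    if n_dup:
        logger.warning("dropped %d duplicate gene symbols", n_dup)
    return list(seen)


@dataclass(frozen=True)
class GeneSignature:
    """Named directional gene set.

    Parameters
    ----------
    name : str
        Label, e.g. ``"SENEVICK"``.
    up_genes, down_genes : sequence of str
        Symbols expected up- / down-regulated in the target state.  Either
        may be empty, but not both.
    """

    name: str
    up_genes: tuple[str, ...] = ()
    down_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        up = tuple(self.up_genes)
        dn = tuple(self.down_genes)
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", dn)
        if not up and not dn:
            raise SignatureError(f"signature {self.name!r} is empty")
        overlap = set(up) & set(dn)
        if overlap:
            raise SignatureError(
                f"signature {self.name!r}: genes in both directions: "
                f"{sorted(overlap)}"
            )
        if len(set(up)) != len(up) or len(set(dn)) != len(dn):
            raise SignatureError(f"signature {self.name!r}: duplicate symbols")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass(frozen=True)
class GeneList:
    """Flat named list of gene symbols (housekeeping, mito, universes)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if not genes:
            raise SignatureError(f"gene list {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise SignatureError(f"gene list {self.name!r}: duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def load_signature(
    path: str | Path,
    dialect: str = "gmt_directional",
    name: str | None = None,
    case_sensitive: bool = False,
) -> GeneSignature:
    """Load a directional signature from a file.

    ``gmt_directional``: a GMT file (tab-separated ``name<TAB>desc<TAB>genes...``)
    containing lines ``<SIG>_UP`` and/or ``<SIG>_DN``.
    ``two_column``: CSV/TSV lines ``symbol,direction`` with direction in
    ``{up, down}`` (header optional).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "gmt_directional":
        return _load_gmt(path, name, case_sensitive)
    if dialect == "two_column":
        return _load_two_column(path, name, case_sensitive)
    raise ValueError(f"unknown dialect {dialect!r}")


def _load_gmt(path: Path, name: str | None, case_sensitive: bool) -> GeneSignature:
    up: list[str] = []
    dn: list[str] = []
    base: str | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SignatureError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        set_name, _desc, *genes = parts
        upper = set_name.upper()
        if upper.endswith("_UP"):
            up.extend(genes)
            stem = set_name[:-3]
        elif upper.endswith(("_DN", "_DOWN")):
            dn.extend(genes)
            stem = set_name[: -3 if upper.endswith("_DN") else -5]
        else:
            raise SignatureError(
                f"{path}:{lineno}: set name {set_name!r} lacks _UP/_DN suffix"
            )
        if base is None:
            base = stem
        elif stem != base:
            raise SignatureError(
                f"{path}: mixed signature stems {base!r} and {stem!r}"
            )
    up_n = _normalize(up, case_sensitive)
    dn_n = _normalize(dn, case_sensitive)
    both = set(up_n) & set(dn_n)
    if both:
        raise SignatureError(f"{path}: genes in both directions: {sorted(both)}")
    return GeneSignature(name or base or path.stem, tuple(up_n), tuple(dn_n))


def _load_two_column(path: Path, name: str | None, case_sensitive: bool) -> GeneSignature:
    up: list[str] = []
    dn: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) != 2:
            raise SignatureError(f"{path}:{lineno}: expected 2 fields")
        sym, direction = parts
        d = direction.lower()
        if lineno == 1 and d not in ("up", "down"):
            continue  # header
        if d == "up":
            up.append(sym)
        elif d in ("down", "dn"):
            dn.append(sym)
        else:
            raise SignatureError(f"{path}:{lineno}: bad direction {direction!r}")
    up_n = _normalize(up, case_sensitive)
    dn_n = _normalize(dn, case_sensitive)
    both = set(up_n) & set(dn_n)
    if both:
        raise SignatureError(f"{path}: genes in both directions: {sorted(both)}")
    return GeneSignature(name or path.stem.upper(), tuple(up_n), tuple(dn_n))


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    """Write a signature in the directional-GMT dialect."""
    path = Path(path)
    lines = []
    if sig.up_genes:
        lines.append("\t".join([f"{sig.name}_UP", "up-regulated", *sig.up_genes]))
    if sig.down_genes:
        lines.append("\t".join([f"{sig.name}_DN", "down-regulated", *sig.down_genes]))
    path.write_text("\n".join(lines) + "\n")


def load_gene_list(path: str | Path, name: str | None = None,
                   case_sensitive: bool = False) -> GeneList:
    """Load a one-symbol-per-line gene list (``#`` comments allowed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    syms = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    return GeneList(name or path.stem, tuple(_normalize(syms, case_sensitive)))


def validate_against_universe(sig: GeneSignature, universe: GeneList) -> dict:
    """Report per-direction coverage of ``sig`` by ``universe``.

    Returns a dict with ``up_coverage``/``down_coverage``/``coverage`` in
    [0, 1] (a direction with no genes reports coverage 1.0 vacuously) and the
    missing symbols.  The signature is never mutated.
    """
    uni = set(universe.genes)
    missing_up = [g for g in sig.up_genes if g not in uni]
    missing_dn = [g for g in sig.down_genes if g not in uni]
    n_up, n_dn = len(sig.up_genes), len(sig.down_genes)
    up_cov = 1.0 if n_up == 0 else 1.0 - len(missing_up) / n_up
    dn_cov = 1.0 if n_dn == 0 else 1.0 - len(missing_dn) / n_dn
    total = n_up + n_dn
    overall = 1.0 - (len(missing_up) + len(missing_dn)) / total
    return {
        "signature": sig.name,
        "up_coverage": up_cov,
        "down_coverage": dn_cov,
        "coverage": overall,
        "missing_up": missing_up,
        "missing_down": missing_dn,
    }


def default_housekeeping() -> GeneList:
    """The packaged default housekeeping gene list."""
    return load_gene_list(
        Path(__file__).parent / "data" / "housekeeping_default.txt",
        name="housekeeping",
    )
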