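"""Data model and delimited-text I/O for volatile compound tables.

Two kinds of input feed the screening pipeline:

* a **compound metadata table** (one row per volatile: identity, chemical
  class, odor threshold in water, GC-O detection flag, Kovats retention
  indices, identification-method flags), and
* a **content matrix** (compound x cultivar x replicate relative contents
  in ug/kg, with explicit not-detected entries).

Conventions: comma-separated UTF-8 text with "." decimal mark; ``n.d.``
marks a censored (below detection) content and ``-`` an absent optional
metadata field. Not-detected contents are *censoring at the detection
limit*; for downstream arithmetic (means, totals, OAV, fold change) they
are valued 0, matching tables in which undetected compounds contribute
nothing, while an explicit "absent" flag keeps present/absent contrasts
distinguishable from small values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CHEM_CLASSES",
    "ID_METHODS",
    "CompoundRecord",
    "CompoundTable",
    "ContentMatrix",
    "CultivarMeans",
    "load_compound_table",
    "load_content_matrix",
    "write_compound_table",
    "write_content_matrix",
    "class_counts",
    "cultivar_means",
    "fixture_compound_path",
    "fixture_content_path",
]

#: Chemical classes a compound row may declare.
CHEM_CLASSES = (
    "aldehyde",
    "ketone",
    "alcohol",
    "ester",
    "hydrocarbon",
    "ether",
    "heterocyclic",
    "other",
)

#: Identification-method flags: mass spectrum, retention index,
#: authentic standard, GC-olfactometry.
ID_METHODS = ("MS", "RI", "STD", "O")

#: Sentinel tokens in delimited files.
ND_TOKEN = "n.d."
MISSING_TOKEN = "-"


@dataclass(frozen=True)
class CompoundRecord:
    """One volatile compound's identity and annotation.

    ``odor_threshold`` is the odor threshold in water (ug/kg) when
    documented; ``gco_detected`` is True iff assessors perceived the
    compound at the sniffing port (equivalently, ``"O" in id_methods``).
    ``ri_exp``/``ri_lit`` are experimental and literature Kovats
    retention indices (dimensionless).
    """

    compound_id: str
    name: str
    chem_class: str
    odor_threshold: float | None = None
    odor_desc_lit: str | None = None
    odor_desc_exp: str | None = None
    gco_detected: bool = False
    ri_exp: float | None = None
    ri_lit: float | None = None
    id_methods: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(
                f"unknown chemical class {self.chem_class!r} for compound "
                f"{self.compound_id!r}; expected one of {CHEM_CLASSES}"
            )
        if self.odor_threshold is not None and not self.odor_threshold > 0:
            raise ValueError(
                f"odor threshold must be > 0, got {self.odor_threshold!r} "
                f"for compound {self.compound_id!r}"
            )
        bad = self.id_methods - set(ID_METHODS)
        if bad:
            raise ValueError(
                f"unknown identification methods {sorted(bad)} for compound "
                f"{self.compound_id!r}"
            )
        if self.gco_detected != ("O" in self.id_methods):
            raise ValueError(
                f"gco_detected flag inconsistent with id_methods for "
                f"compound {self.compound_id!r}: GC-O detection and the 'O' "
                f"flag must agree"
            )


class CompoundTable:
    """Ordered collection of :class:`CompoundRecord` with unique ids."""

    def __init__(self, records: list[CompoundRecord] | tuple[CompoundRecord, ...]):
        ids = [r.compound_id for r in records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate compound_id(s): {sorted(dup)}")
        self.records: tuple[CompoundRecord, ...] = tuple(records)
        self._by_id = {r.compound_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self._by_id[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def __eq__(self, other) -> bool:
        return isinstance(other, CompoundTable) and self.records == other.records

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def id_for_name(self, name: str) -> str:
        """Look up a compound id by its (exact) chemical name."""
        for r in self.records:
            if r.name == name:
                return r.compound_id
        raise KeyError(f"no compound named {name!r}")

    def thresholded(self) -> "CompoundTable":
        """Subset of compounds with a documented odor threshold."""
        return CompoundTable([r for r in self.records if r.odor_threshold is not None])


@dataclass
class ContentMatrix:
    """Replicate-level relative contents (ug/kg), compound x sample.

    ``values`` is indexed by compound_id with a (cultivar, replicate)
    MultiIndex on columns; censored (n.d.) cells hold 0.0 and are False
    in ``detected``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise ValueError("values and detected must share index and columns")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate (cultivar, replicate) sample columns")
        if (self.values.values < 0).any():
            raise ValueError("detected contents must be non-negative")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def cultivars(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def replicates(self, cultivar: str) -> pd.DataFrame:
        """Replicate columns of one cultivar (compound x replicate)."""
        if cultivar not in self.cultivars:
            raise ValueError(f"cultivar {cultivar!r} not present")
        return self.values[cultivar]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContentMatrix)
            and self.values.equals(other.values)
            and self.detected.equals(other.detected)
        )


@dataclass
class CultivarMeans:
    """Per-cultivar mean contents (ug/kg) with an all-replicates-n.d. flag."""

    values: pd.DataFrame  # compound x cultivar
    absent: pd.DataFrame  # True where every replicate was n.d.

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def cultivars(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _opt_str(cell: str) -> str | None:
    return None if cell == MISSING_TOKEN or cell == "" else cell


def _opt_float(cell: str, *, what: str, row: str) -> float | None:
    if cell in (MISSING_TOKEN, ""):
        return None
    if cell == ND_TOKEN:
        raise ValueError(
            f"'n.d.' is a content-matrix token and is not allowed in the "
            f"{what} column (row {row})"
        )
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"non-numeric {what} {cell!r} in row {row}") from None


def load_compound_table(path: str | Path) -> CompoundTable:
    """Read a compound metadata table from ``compounds.csv`` format.

    Columns: compound_id, name, chem_class, odor_threshold, odor_desc_lit,
    odor_desc_exp, gco_detected, ri_exp, ri_lit, id_methods (semicolon
    joined). ``-`` marks an absent optional field. Duplicate ids and
    unknown class labels are hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "compound_id",
        "name",
        "chem_class",
        "odor_threshold",
        "odor_desc_lit",
        "odor_desc_exp",
        "gco_detected",
        "ri_exp",
        "ri_lit",
        "id_methods",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing column(s): {sorted(missing)}")

    records = []
    for _, row in df.iterrows():
        cid = row["compound_id"]
        methods = frozenset(m for m in row["id_methods"].split(";") if m)
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=row["name"],
                chem_class=row["chem_class"],
                odor_threshold=_opt_float(row["odor_threshold"], what="odor_threshold", row=cid),
                odor_desc_lit=_opt_str(row["odor_desc_lit"]),
                odor_desc_exp=_opt_str(row["odor_desc_exp"]),
                gco_detected=row["gco_detected"].strip().lower() in ("true", "1", "yes"),
                ri_exp=_opt_float(row["ri_exp"], what="ri_exp", row=cid),
                ri_lit=_opt_float(row["ri_lit"], what="ri_lit", row=cid),
                id_methods=methods,
            )
        )
    return CompoundTable(records)


def write_compound_table(table: CompoundTable, path: str | Path) -> None:
    """Write a compound table in the same format ``load_compound_table`` reads."""

    def fmt_opt(x) -> str:
        if x is None:
            return MISSING_TOKEN
        if isinstance(x, float):
            return format(x, "g")
        return str(x)

    rows = []
    for r in table:
        rows.append(
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "chem_class": r.chem_class,
                "odor_threshold": fmt_opt(r.odor_threshold),
                "odor_desc_lit": fmt_opt(r.odor_desc_lit),
                "odor_desc_exp": fmt_opt(r.odor_desc_exp),
                "gco_detected": "true" if r.gco_detected else "false",
                "ri_exp": fmt_opt(r.ri_exp),
                "ri_lit": fmt_opt(r.ri_lit),
                "id_methods": ";".join(m for m in ID_METHODS if m in r.id_methods),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_content_matrix(path: str | Path) -> ContentMatrix:
    """Read a long-format content matrix (compound_id,cultivar,replicate,content).

    ``n.d.`` cells become censored entries (0.0 with detected=False);
    negative or non-numeric non-``n.d.`` contents are hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"compound_id", "cultivar", "replicate", "content"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"content matrix missing column(s): {sorted(missing)}")

    vals: dict[tuple[str, int], dict[str, float]] = {}
    det: dict[tuple[str, int], dict[str, bool]] = {}
    compounds: list[str] = []
    seen_cells = set()
    for _, row in df.iterrows():
        cid, cultivar = row["compound_id"], row["cultivar"]
        rep = int(row["replicate"])
        cell = row["content"]
        key = (cid, cultivar, rep)
        if key in seen_cells:
            raise ValueError(f"duplicate content cell for {key}")
        seen_cells.add(key)
        if cid not in compounds:
            compounds.append(cid)
        if cell == ND_TOKEN:
            value, detected = 0.0, False
        else:
            try:
                value = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric content {cell!r} for compound {cid} "
                    f"({cultivar} rep {rep}); only numbers or 'n.d.' allowed"
                ) from None
            if value < 0:
                raise ValueError(
                    f"negative content {value} for compound {cid} ({cultivar} rep {rep})"
                )
            detected = True
        vals.setdefault((cultivar, rep), {})[cid] = value
        det.setdefault((cultivar, rep), {})[cid] = detected

    columns = pd.MultiIndex.from_tuples(sorted(vals), names=["cultivar", "replicate"])
    values = pd.DataFrame(
        {c: pd.Series(vals[c]) for c in columns}, index=compounds, columns=columns
    )
    detected = pd.DataFrame(
        {c: pd.Series(det[c]) for c in columns}, index=compounds, columns=columns
    )
    if values.isna().any().any():
        holes = values.isna().stack(future_stack=True)
        raise ValueError(f"ragged content matrix: missing cells {holes[holes].index.tolist()[:5]}")
    return ContentMatrix(values=values.astype(float), detected=detected.astype(bool))


def write_content_matrix(matrix: ContentMatrix, path: str | Path) -> None:
    """Write long-format CSV; censored cells rendered as ``n.d.``.

    Values are written with ``repr`` round-trip precision so that
    read -> write -> read is lossless.
    """
    buf = io.StringIO()
    buf.write("compound_id,cultivar,replicate,content\n")
    for cultivar, rep in matrix.values.columns:
        for cid in matrix.compounds:
            if matrix.detected.loc[cid, (cultivar, rep)]:
                cell = repr(float(matrix.values.loc[cid, (cultivar, rep)]))
            else:
                cell = ND_TOKEN
            buf.write(f"{cid},{cultivar},{rep},{cell}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# aggregation


def class_counts(table: CompoundTable) -> dict[str, int]:
    """Number of compounds per chemical class (classes with zero omitted)."""
    counts: dict[str, int] = {}
    for r in table:
        counts[r.chem_class] = counts.get(r.chem_class, 0) + 1
    return counts


def cultivar_means(matrix: ContentMatrix) -> CultivarMeans:
    """Arithmetic replicate means per compound and cultivar.

    n.d. replicates count as 0 in the mean; a compound undetected in every
    replicate of a cultivar has mean 0 and is flagged absent. The result is
    invariant under permutation of replicate order.
    """
    cultivars = matrix.cultivars
    means = {}
    absent = {}
    for cv in cultivars:
        reps = matrix.replicates(cv)
        if reps.shape[1] == 0:
            raise ValueError(f"cultivar {cv!r} has zero replicates")
        means[cv] = reps.mean(axis=1)
        absent[cv] = ~matrix.detected[cv].any(axis=1)
    values = pd.DataFrame(means, index=matrix.compounds, columns=cultivars)
    flags = pd.DataFrame(absent, index=matrix.compounds, columns=cultivars)
    return CultivarMeans(values=values, absent=flags)


# ---------------------------------------------------------------------------
# packaged fixture (cultivar-level means serialized as single replicates)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("aromascreen").joinpath("data", name)))


def fixture_compound_path() -> Path:
    """Path of the packaged 45-compound metadata fixture."""
    return _data_path("compounds.csv")


def fixture_content_path() -> Path:
    """Path of the packaged per-cultivar content fixture (single replicate)."""
    return _data_path("contents.csv")
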