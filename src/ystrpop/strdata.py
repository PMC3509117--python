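"""Data model and I/O for Y-STR haplotype tables.

A Y-STR haplotype is a vector of integer repeat counts, one per locus of a
:class:`LocusPanel` (e.g. the 17-locus Yfiler panel).  Populations are
labelled multisets of haplotypes; a :class:`Dataset` bundles populations
sharing one panel, plus a population→group assignment.

Input tables are delimited text with a header row naming the loci and the
reserved columns ``population``, ``group`` (optional) and ``count``
(optional; one row per distinct haplotype instead of one row per
individual).
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LocusPanel",
    "STRHaplotype",
    "PopulationSample",
    "Dataset",
    "PanelRules",
    "YFILER_17",
    "YFILER_15_ANALYSIS",
    "DEFAULT_PANEL_RULES",
    "HaplotypeParseError",
    "read_haplotype_table",
    "write_haplotype_table",
    "derive_analysis_panel",
    "apply_panel_rules",
    "haplogroup_frequency",
]

RESERVED_COLUMNS = ("population", "group", "count")


class HaplotypeParseError(ValueError):
    """Raised when a haplotype table cannot be parsed or validated."""


@dataclass(frozen=True)
class LocusPanel:
    """An ordered set of named Y-STR loci."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ValueError("panel needs at least one locus")
        if len(set(self.names)) != len(self.names):
            dupes = [n for n, c in Counter(self.names).items() if c > 1]
            raise ValueError(f"duplicate locus names: {dupes}")

    @property
    def L(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"locus {name!r} not in panel {list(self.names)}") from None


#: The 17 loci of the AmpFlSTR Yfiler multiplex.
YFILER_17 = LocusPanel((
    "DYS456", "DYS389I", "DYS390", "DYS389II", "DYS458", "DYS19",
    "DYS385a", "DYS385b", "DYS393", "DYS391", "DYS439", "DYS635",
    "DYS392", "YGATAH4", "DYS437", "DYS438", "DYS448",
))


@dataclass(frozen=True, order=True)
class STRHaplotype:
    """Repeat counts at each locus of a panel, in panel order.

    Equality and ordering are elementwise on the repeat vector; ordering is
    used only for deterministic tie-breaking.
    """

    repeats: tuple[int, ...]

    def __post_init__(self) -> None:
        import numbers

        reps = []
        for r in self.repeats:
            if not isinstance(r, numbers.Integral) or r < 0:
                raise ValueError(
                    f"repeat counts must be non-negative integers: {self.repeats}")
            reps.append(int(r))
        object.__setattr__(self, "repeats", tuple(reps))

    def __len__(self) -> int:
        return len(self.repeats)


@dataclass
class PopulationSample:
    """A labelled multiset of haplotypes from one population."""

    name: str
    haplotypes: Counter
    group: str = ""
    panel: LocusPanel | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.haplotypes, Counter):
            self.haplotypes = Counter(self.haplotypes)
        if self.n < 1:
            raise ValueError(f"population {self.name!r} is empty")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) > 1:
            raise ValueError(f"population {self.name!r} mixes haplotype lengths {sorted(lengths)}")
        if self.panel is not None and lengths and lengths != {self.panel.L}:
            raise ValueError(
                f"population {self.name!r}: haplotype length {lengths.pop()} "
                f"!= panel size {self.panel.L}"
            )

    @property
    def n(self) -> int:
        """Total sample size (sum of multiplicities)."""
        return sum(self.haplotypes.values())

    @property
    def h(self) -> int:
        """Number of distinct haplotypes."""
        return len(self.haplotypes)

    def distinct(self) -> list[STRHaplotype]:
        """Distinct haplotypes in deterministic (lexicographic) order."""
        return sorted(self.haplotypes)

    def to_arrays(self):
        """Return ``(matrix, counts)``: distinct haplotypes as an ``h x L``
        int array (lexicographic row order) and their multiplicities."""
        import numpy as np

        haps = self.distinct()
        mat = np.array([h.repeats for h in haps], dtype=np.int64)
        counts = np.array([self.haplotypes[h] for h in haps], dtype=np.int64)
        return mat, counts

    def expand(self):
        """Return the full ``n x L`` matrix, one row per individual."""
        import numpy as np

        mat, counts = self.to_arrays()
        return np.repeat(mat, counts, axis=0)


@dataclass
class Dataset:
    """Populations sharing one locus panel."""

    panel: LocusPanel
    populations: list[PopulationSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate population names: {names}")
        for p in self.populations:
            for h in p.haplotypes:
                if len(h) != self.panel.L:
                    raise ValueError(
                        f"population {p.name!r}: haplotype length {len(h)} "
                        f"!= panel size {self.panel.L}"
                    )
            p.panel = self.panel

    @property
    def group_map(self) -> dict[str, str]:
        return {p.name: p.group for p in self.populations}

    def population(self, name: str) -> PopulationSample:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"no population named {name!r}")

    def subset(self, names: Iterable[str]) -> "Dataset":
        names = list(names)
        return Dataset(self.panel, [self.population(n) for n in names])

    def pooled(self, names: Iterable[str], label: str) -> PopulationSample:
        """Merge several populations into one sample (multiplicities add)."""
        c: Counter = Counter()
        for n in names:
            c.update(self.population(n).haplotypes)
        return PopulationSample(label, c, group=label, panel=self.panel)

    @property
    def n_total(self) -> int:
        return sum(p.n for p in self.populations)


# ---------------------------------------------------------------------------
# table I/O

def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_haplotype_table(
    path,
    *,
    delimiter: str | None = None,
    panel: LocusPanel | None = None,
    missing: str = "drop",
) -> Dataset:
    """Read a delimited haplotype table into a :class:`Dataset`.

    Parameters
    ----------
    path
        File path (or file-like object) of a UTF-8 text table.  The header
        names the loci; ``population``/``group``/``count`` columns are
        recognised.  Tab delimiter is the default, comma is auto-detected.
    panel
        If given, the table's locus columns must match this panel exactly.
    missing
        ``"drop"`` (default) discards rows with missing repeat values with a
        warning; ``"strict"`` raises instead.
    """
    if missing not in ("drop", "strict"):
        raise ValueError("missing must be 'drop' or 'strict'")

    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise HaplotypeParseError(f"empty haplotype table: {path}")
    sep = delimiter or _detect_delimiter(lines[0])
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep=sep, dtype=str)

    cols = list(df.columns)
    loci = [c for c in cols if c.lower() not in RESERVED_COLUMNS]
    if not loci:
        raise HaplotypeParseError("no locus columns found in header")
    file_panel = LocusPanel(tuple(loci))
    if panel is not None:
        unknown = [c for c in loci if c not in panel.names]
        if unknown or set(loci) != set(panel.names):
            raise HaplotypeParseError(
                f"locus columns {loci} do not match panel {list(panel.names)}"
            )
        file_panel = panel
        loci = list(panel.names)

    colmap = {c.lower(): c for c in cols}
    pop_col = colmap.get("population")
    grp_col = colmap.get("group")
    cnt_col = colmap.get("count")

    pops: dict[str, Counter] = {}
    groups: dict[str, str] = {}
    order: list[str] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        values = [row[l] for l in loci]
        if any(pd.isna(v) or str(v).strip() == "" for v in values):
            if missing == "strict":
                raise HaplotypeParseError(f"row {idx + 2}: missing repeat value")
            n_dropped += 1
            continue
        repeats = []
        for locus, v in zip(loci, values):
            s = str(v).strip()
            try:
                r = int(s)
            except ValueError:
                raise HaplotypeParseError(
                    f"row {idx + 2}, locus {locus}: non-integer repeat value {s!r}"
                ) from None
            if r < 0:
                raise HaplotypeParseError(
                    f"row {idx + 2}, locus {locus}: negative repeat value {r}"
                )
            repeats.append(r)
        hap = STRHaplotype(tuple(repeats))
        pop = str(row[pop_col]).strip() if pop_col else "pop1"
        grp = str(row[grp_col]).strip() if grp_col and not pd.isna(row[grp_col]) else ""
        count = 1
        if cnt_col is not None and not pd.isna(row[cnt_col]):
            try:
                count = int(str(row[cnt_col]).strip())
            except ValueError:
                raise HaplotypeParseError(f"row {idx + 2}: non-integer count") from None
            if count < 1:
                raise HaplotypeParseError(f"row {idx + 2}: count must be >= 1")
        pops.setdefault(pop, Counter())[hap] += count
        if pop not in order:
            order.append(pop)
        if grp:
            groups[pop] = grp

    if n_dropped:
        warnings.warn(f"dropped {n_dropped} row(s) with missing repeat values", stacklevel=2)
    if not pops:
        raise HaplotypeParseError("no complete haplotype rows in table")

    populations = [
        PopulationSample(name, pops[name], group=groups.get(name, ""), panel=file_panel)
        for name in order
    ]
    return Dataset(file_panel, populations)


def write_haplotype_table(dataset: Dataset, path, *, delimiter: str = "\t",
                          per_individual: bool = False, header_comment: str | None = None) -> None:
    """Write a :class:`Dataset` as a delimited text table.

    By default one row per distinct haplotype with a ``count`` column;
    ``per_individual=True`` writes one row per individual instead.
    """
    rows = []
    for pop in dataset.populations:
        for hap in pop.distinct():
            c = pop.haplotypes[hap]
            base = {"population": pop.name, "group": pop.group}
            base.update(dict(zip(dataset.panel.names, hap.repeats)))
            if per_individual:
                rows.extend([dict(base) for _ in range(c)])
            else:
                base["count"] = c
                rows.append(base)
    cols = ["population", "group", *dataset.panel.names] + ([] if per_individual else ["count"])
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# panel derivation

@dataclass(frozen=True)
class PanelRules:
    """Rules deriving an analysis panel from a raw genotyping panel.

    ``exclude`` drops loci (multicopy loci are unusable in step-based
    statistics); ``subtract`` replaces a composite locus by its value minus a
    nested locus (DYS389II physically contains DYS389I, so the independent
    repeat count is the difference).
    """

    exclude: tuple[str, ...] = ()
    subtract: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "subtract", dict(self.subtract))


#: Standard Yfiler practice: drop the multicopy DYS385a/b pair (17 -> 15 loci)
#: and score DYS389II as DYS389II - DYS389I.
DEFAULT_PANEL_RULES = PanelRules(
    exclude=("DYS385a", "DYS385b"),
    subtract={"DYS389II": "DYS389I"},
)

YFILER_15_ANALYSIS = LocusPanel(tuple(n for n in YFILER_17.names if n not in ("DYS385a", "DYS385b")))


def derive_analysis_panel(raw_panel: LocusPanel, rules: PanelRules = DEFAULT_PANEL_RULES) -> LocusPanel:
    """Apply exclusion/adjustment rules to a raw panel; returns the analysis panel.

    Subtraction rules do not change locus names or order, so the derived
    panel is simply the raw panel minus the excluded loci.
    """
    for locus in rules.exclude:
        raw_panel.index(locus)  # raises KeyError if absent
    for composite, nested in rules.subtract.items():
        raw_panel.index(composite)
        raw_panel.index(nested)
    return LocusPanel(tuple(n for n in raw_panel.names if n not in rules.exclude))


def apply_panel_rules(dataset: Dataset, rules: PanelRules = DEFAULT_PANEL_RULES) -> Dataset:
    """Transform a dataset onto its analysis panel (see :class:`PanelRules`)."""
    new_panel = derive_analysis_panel(dataset.panel, rules)
    sub_idx = {
        dataset.panel.index(comp): dataset.panel.index(nested)
        for comp, nested in rules.subtract.items()
    }
    keep = [i for i, n in enumerate(dataset.panel.names) if n not in rules.exclude]
    new_pops = []
    for pop in dataset.populations:
        c: Counter = Counter()
        for hap, mult in pop.haplotypes.items():
            r = list(hap.repeats)
            for ci, ni in sub_idx.items():
                adj = r[ci] - hap.repeats[ni]
                if adj < 0:
                    raise HaplotypeParseError(
                        f"population {pop.name!r}: composite adjustment yields negative "
                        f"repeat count at locus {dataset.panel.names[ci]}"
                    )
                r[ci] = adj
            c[STRHaplotype(tuple(r[i] for i in keep))] += mult
        new_pops.append(PopulationSample(pop.name, c, group=pop.group, panel=new_panel))
    return Dataset(new_panel, new_pops)


# ---------------------------------------------------------------------------
# haplogroup frequencies

def haplogroup_frequency(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-population carrier frequency of a haplogroup.

    ``counts`` needs columns ``population``, ``carriers``, ``total``; returns
    the same table with a ``frequency`` column in [0, 1].
    """
    df = counts.copy()
    for col in ("population", "carriers", "total"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    df["carriers"] = df["carriers"].astype(int)
    df["total"] = df["total"].astype(int)
    if (df["total"] < 1).any():
        raise ValueError("total typed males must be >= 1")
    if (df["carriers"] < 0).any():
        raise ValueError("carrier counts must be >= 0")
    bad = df[df["carriers"] > df["total"]]
    if not bad.empty:
        raise ValueError(f"carriers > total for population(s) {list(bad['population'])}")
    df["frequency"] = df["carriers"] / df["total"]
    return df
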