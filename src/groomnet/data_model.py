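"""Domain types and file formats for scan-sampling grooming observations.

The observational unit is the *group scan*: at each scan every visible adult's
instantaneous behavior is recorded.  A grooming record is an ordered
(actor, receiver) pair within one scan; a mutual grooming bout is stored as two
ordered pairs.  Visibility is recorded per individual per scan; whether a dyad
was jointly unobservable is derived downstream, never stored.

Individuals are recorded once per group observation period, so an individual
that was observed in several compositionally different groups contributes one
:class:`IndividualRecord` per group, each with its own age.

File formats (all plain text / XLSX):

* scan table -- long-format delimited text, one row per individual per scan,
  columns ``group_id, scan_index, individual_id, sex, age, rearing, visible,
  behavior, partner_id``.
* agonistic table -- delimited text with ``group_id, winner_id, loser_id``.
* adjacency -- labeled square CSV (row actor, column receiver).
* supplementary workbook -- XLSX with a ``groups`` sheet, an ``individuals``
  sheet (metadata plus the five published network-metric values) and one
  ``matrix_<group>`` sheet per group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
REARING_CATEGORIES = ("mother_reared", "atypically_reared")
GROOMING = "grooming"

METRIC_COLUMNS = ("out_strength", "in_strength", "disparity", "affinity",
                  "eigenvector")

SCAN_TABLE_COLUMNS = ("group_id", "scan_index", "individual_id", "sex", "age",
                      "rearing", "visible", "behavior", "partner_id")


class ParseError(ValueError):
    """A file could not be parsed into rows (names the offending row)."""


class ValidationError(ValueError):
    """Parsed rows violate a domain invariant."""


class FormatError(ValueError):
    """A structured input (matrix, workbook) has an inconsistent layout."""


@dataclass(frozen=True)
class IndividualRecord:
    """One adult individual observed in one group composition."""

    individual_id: str
    group_id: str
    sex: str
    age: float
    rearing: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r} for "
                                  f"{self.individual_id}")
        if self.rearing not in REARING_CATEGORIES:
            raise ValidationError(f"unknown rearing {self.rearing!r} for "
                                  f"{self.individual_id}")
        if not (self.age >= 0 and math.isfinite(self.age)):
            raise ValidationError(f"invalid age {self.age!r} for "
                                  f"{self.individual_id}")


@dataclass(frozen=True)
class GroupRecord:
    """A compositionally distinct group of adults."""

    group_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError(f"group {self.group_id} has "
                                  f"{len(self.members)} member(s); need >= 2")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"duplicate members in group {self.group_id}")

    @property
    def group_size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ScanEvent:
    """One instantaneous group scan.

    ``grooming_pairs`` holds ordered (actor, receiver) pairs; a mutual bout is
    two pairs.  ``out_of_sight`` lists individuals invisible during this scan.
    """

    group_id: str
    scan_index: int
    grooming_pairs: frozenset[tuple[str, str]] = frozenset()
    out_of_sight: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for actor, receiver in self.grooming_pairs:
            if actor == receiver:
                raise ValidationError(
                    f"self-grooming pair ({actor}) in group {self.group_id} "
                    f"scan {self.scan_index}")


@dataclass
class ObservationSet:
    """All observations for one or more groups, referentially validated."""

    individuals: list[IndividualRecord]
    groups: list[GroupRecord]
    scans: list[ScanEvent] = field(default_factory=list)
    agonistic_events: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    def group(self, group_id: str) -> GroupRecord:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"unknown group {group_id!r}")

    def members(self, group_id: str) -> tuple[str, ...]:
        return self.group(group_id).members

    def record(self, group_id: str, individual_id: str) -> IndividualRecord:
        for rec in self.individuals:
            if rec.group_id == group_id and rec.individual_id == individual_id:
                return rec
        raise KeyError(f"no record for {individual_id!r} in {group_id!r}")

    def records_for(self, group_id: str) -> list[IndividualRecord]:
        return [r for r in self.individuals if r.group_id == group_id]

    def scans_for(self, group_id: str) -> list[ScanEvent]:
        return [s for s in self.scans if s.group_id == group_id]

    def events_for(self, group_id: str) -> list[tuple[str, str]]:
        return [(w, l) for g, w, l in self.agonistic_events if g == group_id]

    def sex_counts(self, group_id: str) -> tuple[int, int]:
        """(n_males, n_females) among adult members."""
        recs = self.records_for(group_id)
        males = sum(r.sex == "male" for r in recs)
        return males, len(recs) - males

    def sex_ratio(self, group_id: str) -> float:
        males, females = self.sex_counts(group_id)
        if females == 0:
            return math.inf
        return males / females

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        group_members: dict[str, set[str]] = {}
        for g in self.groups:
            if g.group_id in group_members:
                raise ValidationError(f"duplicate group id {g.group_id!r}")
            group_members[g.group_id] = set(g.members)

        seen_records: set[tuple[str, str]] = set()
        for rec in self.individuals:
            if rec.group_id not in group_members:
                raise ValidationError(
                    f"record {rec.individual_id!r} references unknown group "
                    f"{rec.group_id!r}")
            if rec.individual_id not in group_members[rec.group_id]:
                raise ValidationError(
                    f"{rec.individual_id!r} is not a member of "
                    f"{rec.group_id!r}")
            key = (rec.group_id, rec.individual_id)
            if key in seen_records:
                raise ValidationError(f"duplicate individual record {key}")
            seen_records.add(key)
        for gid, members in group_members.items():
            recorded = {r.individual_id for r in self.individuals
                        if r.group_id == gid}
            if recorded != members:
                missing = members - recorded
                raise ValidationError(
                    f"group {gid!r}: members without metadata: "
                    f"{sorted(missing)}")

        seen_scans: set[tuple[str, int]] = set()
        for scan in self.scans:
            if scan.group_id not in group_members:
                raise ValidationError(
                    f"scan references unknown group {scan.group_id!r}")
            key = (scan.group_id, scan.scan_index)
            if key in seen_scans:
                raise ValidationError(f"duplicate scan index {key}")
            seen_scans.add(key)
            members = group_members[scan.group_id]
            for actor, receiver in scan.grooming_pairs:
                if actor not in members or receiver not in members:
                    raise ValidationError(
                        f"scan {key}: grooming pair ({actor}, {receiver}) "
                        f"outside group membership")
            if not scan.out_of_sight <= members:
                raise ValidationError(
                    f"scan {key}: out-of-sight ids outside group membership")

        for gid, winner, loser in self.agonistic_events:
            if gid not in group_members:
                raise ValidationError(
                    f"agonistic event references unknown group {gid!r}")
            if winner not in group_members[gid] or loser not in group_members[gid]:
                raise ValidationError(
                    f"agonistic event ({winner}, {loser}) outside group "
                    f"{gid!r}")
            if winner == loser:
                raise ValidationError(
                    f"agonistic event with winner == loser ({winner})")


# ---------------------------------------------------------------------------
# scan tables
# ---------------------------------------------------------------------------

def write_scan_table(obs: ObservationSet, path: str | Path,
                     sep: str = ",") -> None:
    """Write the long-format scan table (one row per individual per scan)."""
    rows = []
    for scan in obs.scans:
        groomed: dict[str, str] = {}
        for actor, receiver in sorted(scan.grooming_pairs):
            if actor in groomed:
                logger.warning("scan (%s, %d): actor %s grooms more than one "
                               "receiver; keeping first",
                               scan.group_id, scan.scan_index, actor)
                continue
            groomed[actor] = receiver
        for iid in obs.members(scan.group_id):
            rec = obs.record(scan.group_id, iid)
            receiver = groomed.get(iid, "")
            rows.append({
                "group_id": scan.group_id,
                "scan_index": scan.scan_index,
                "individual_id": iid,
                "sex": rec.sex,
                "age": rec.age,
                "rearing": rec.rearing,
                "visible": 0 if iid in scan.out_of_sight else 1,
                "behavior": GROOMING if receiver else "",
                "partner_id": receiver,
            })
    pd.DataFrame(rows, columns=list(SCAN_TABLE_COLUMNS)).to_csv(
        path, sep=sep, index=False)


def read_scan_table(path: str | Path, sep: str = ",") -> ObservationSet:
    """Read a long-format scan table and build a validated ObservationSet.

    Rows whose partner id does not resolve to a group member are rejected and
    reported (logged); malformed rows raise :class:`ParseError` naming the row.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - passthrough
        raise ParseError(f"cannot read scan table {path}: {exc}") from exc
    missing = set(SCAN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"scan table {path} lacks columns {sorted(missing)}")

    for col, caster in (("scan_index", int), ("age", float), ("visible", int)):
        try:
            df[col] = df[col].map(caster)
        except (TypeError, ValueError) as exc:
            bad = df.index[~df[col].map(_castable(caster))][0]
            raise ParseError(
                f"scan table {path}, row {bad + 2}: bad {col} value "
                f"{df.loc[bad, col]!r}") from exc

    dup = df.duplicated(subset=["group_id", "scan_index", "individual_id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValidationError(
            f"scan table {path}: duplicate (group, scan, individual) at "
            f"row {row}")
    if (df["individual_id"] == df["partner_id"]).any():
        row = int(df.index[df["individual_id"] == df["partner_id"]][0]) + 2
        raise ValidationError(
            f"scan table {path}: actor equals receiver at row {row}")

    individuals: list[IndividualRecord] = []
    groups: list[GroupRecord] = []
    rejected: list[int] = []
    scans: list[ScanEvent] = []
    for gid, gdf in df.groupby("group_id", sort=True):
        meta = gdf.drop_duplicates(subset="individual_id")
        for _, r in meta.iterrows():
            conflicting = gdf[gdf["individual_id"] == r["individual_id"]]
            if (conflicting["sex"].nunique() > 1
                    or conflicting["rearing"].nunique() > 1):
                raise ValidationError(
                    f"scan table {path}: inconsistent traits for "
                    f"{r['individual_id']!r} in group {gid!r}")
            individuals.append(IndividualRecord(
                individual_id=str(r["individual_id"]), group_id=str(gid),
                sex=str(r["sex"]), age=float(r["age"]),
                rearing=str(r["rearing"])))
        members = tuple(meta["individual_id"])
        groups.append(GroupRecord(group_id=str(gid), members=members))
        member_set = set(members)
        for scan_index, sdf in gdf.groupby("scan_index", sort=True):
            pairs = []
            out = []
            for idx, r in sdf.iterrows():
                if not r["visible"]:
                    out.append(r["individual_id"])
                if r["behavior"] == GROOMING:
                    if r["partner_id"] not in member_set:
                        rejected.append(int(idx) + 2)
                        continue
                    pairs.append((r["individual_id"], r["partner_id"]))
            scans.append(ScanEvent(
                group_id=str(gid), scan_index=int(scan_index),
                grooming_pairs=frozenset(pairs), out_of_sight=frozenset(out)))
    if rejected:
        logger.warning("scan table %s: rejected %d row(s) with unresolvable "
                       "partner ids (rows %s)", path, len(rejected),
                       rejected[:20])
    return ObservationSet(individuals=individuals, groups=groups, scans=scans)


def _castable(caster):
    def ok(value) -> bool:
        try:
            caster(value)
            return True
        except (TypeError, ValueError):
            return False
    return ok


# ---------------------------------------------------------------------------
# agonistic tables
# ---------------------------------------------------------------------------

def write_agonistic_table(events: Iterable[tuple[str, str, str]],
                          path: str | Path) -> None:
    pd.DataFrame(list(events),
                 columns=["group_id", "winner_id", "loser_id"]).to_csv(
        path, index=False)


def read_agonistic_table(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"group_id", "winner_id", "loser_id"} - set(df.columns)
    if missing:
        raise ParseError(
            f"agonistic table {path} lacks columns {sorted(missing)}")
    return [tuple(r) for r in
            df[["group_id", "winner_id", "loser_id"]].itertuples(index=False)]


# ---------------------------------------------------------------------------
# adjacency matrices
# ---------------------------------------------------------------------------

def write_adjacency(nodes: Sequence[str], W: np.ndarray,
                    path: str | Path) -> None:
    """Write a labeled square adjacency CSV (weights round-trip exactly)."""
    W = np.asarray(W, dtype=float)
    if W.shape != (len(nodes), len(nodes)):
        raise FormatError(f"matrix shape {W.shape} does not match "
                          f"{len(nodes)} node labels")
    pd.DataFrame(W, index=list(nodes), columns=list(nodes)).to_csv(path)


def read_adjacency(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise FormatError(f"adjacency {path}: row labels differ from column "
                          f"labels")
    W = df.to_numpy(dtype=float)
    if W.shape[0] != W.shape[1]:
        raise FormatError(f"adjacency {path}: matrix is not square")
    if not np.isfinite(W).all():
        raise FormatError(f"adjacency {path}: non-finite weights")
    return rows, W


# ---------------------------------------------------------------------------
# supplementary workbook (S1-style layout)
# ---------------------------------------------------------------------------

@dataclass
class WorkbookData:
    """Parsed supplementary workbook.

    ``individuals`` carries one row per individual-in-group with metadata and
    the published five metric values (NaN where a metric was not defined);
    ``groups`` carries group-level covariates; ``matrices`` maps group id to
    (node labels, weighted adjacency).
    """

    individuals: pd.DataFrame
    groups: pd.DataFrame
    matrices: dict[str, tuple[list[str], np.ndarray]]


def write_supplementary_workbook(path: str | Path,
                                 individuals: pd.DataFrame,
                                 groups: pd.DataFrame,
                                 matrices: Mapping[str, tuple[Sequence[str],
                                                              np.ndarray]],
                                 ) -> None:
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        groups.to_excel(writer, sheet_name="groups", index=False)
        individuals.to_excel(writer, sheet_name="individuals", index=False)
        for gid, (nodes, W) in matrices.items():
            pd.DataFrame(np.asarray(W, dtype=float), index=list(nodes),
                         columns=list(nodes)).to_excel(
                writer, sheet_name=f"matrix_{gid}"[:31])


def _decomma(series: pd.Series) -> pd.Series:
    """Coerce numbers written with a decimal comma (European exports)."""
    if series.dtype == object:
        return pd.to_numeric(
            series.astype(str).str.replace(",", ".", regex=False)
            .replace({"": np.nan, "nan": np.nan, "NA": np.nan}),
            errors="raise")
    return pd.to_numeric(series, errors="raise")


def read_supplementary_workbook(path: str | Path) -> WorkbookData:
    """Read an S1-layout workbook: metadata sheets plus per-group matrices."""
    sheets = pd.read_excel(path, sheet_name=None, index_col=None)
    if "groups" not in sheets or "individuals" not in sheets:
        raise FormatError(f"workbook {path}: missing 'groups'/'individuals' "
                          f"sheet")
    groups = sheets["groups"].copy()
    individuals = sheets["individuals"].copy()
    groups["group_id"] = groups["group_id"].astype(str)
    individuals["group_id"] = individuals["group_id"].astype(str)
    individuals["individual_id"] = individuals["individual_id"].astype(str)
    for col in ("group_size", "n_scans"):
        if col in groups:
            groups[col] = _decomma(groups[col]).astype(int)
    if "sex_ratio" in groups:
        groups["sex_ratio"] = _decomma(groups["sex_ratio"])
    individuals["age"] = _decomma(individuals["age"]).astype(float)
    for col in METRIC_COLUMNS:
        if col in individuals:
            individuals[col] = _decomma(individuals[col]).astype(float)

    matrices: dict[str, tuple[list[str], np.ndarray]] = {}
    for name, sheet in sheets.items():
        if not name.startswith("matrix_"):
            continue
        gid = name[len("matrix_"):]
        sheet = sheet.set_index(sheet.columns[0])
        nodes = [str(i) for i in sheet.index]
        cols = [str(c) for c in sheet.columns]
        if nodes != cols:
            raise FormatError(f"workbook {path}, sheet {name}: row/column "
                              f"labels differ")
        W = sheet.apply(_decomma).to_numpy(dtype=float)
        if W.shape[0] != W.shape[1]:
            raise FormatError(f"workbook {path}, sheet {name}: not square")
        matrices[gid] = (nodes, W)

    for gid in groups["group_id"]:
        if gid not in matrices:
            raise FormatError(f"workbook {path}: no matrix sheet for group "
                              f"{gid!r}")
        nodes, _ = matrices[gid]
        listed = set(individuals.loc[individuals["group_id"] == gid,
                                     "individual_id"])
        if listed != set(nodes):
            raise FormatError(f"workbook {path}: matrix labels for {gid!r} "
                              f"disagree with the individuals sheet")
    return WorkbookData(individuals=individuals, groups=groups,
                        matrices=matrices)


def observation_metadata_from_workbook(data: WorkbookData) -> ObservationSet:
    """Build the metadata-only ObservationSet (no scans) from a workbook."""
    individuals = [IndividualRecord(individual_id=r.individual_id,
                                    group_id=r.group_id, sex=r.sex,
                                    age=float(r.age), rearing=r.rearing)
                   for r in data.individuals.itertuples(index=False)]
    groups = []
    for gid, (nodes, _) in data.matrices.items():
        groups.append(GroupRecord(group_id=gid, members=tuple(nodes)))
    return ObservationSet(individuals=individuals, groups=groups)
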