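"""Data model and delimited-text I/O for camera-trap capture-recapture data.

A *site* is one camera-trap location (paired cameras photographing both
flanks of a passing animal count as a single proximity detector).  Effort is
recorded as a binary activity mask over *occasions*; daily effort tables are
collapsed to occasions of ``occasion_length`` successive trap nights.
Encounters are binary per individual x site x occasion: repeated photographs
of one individual at one site within one occasion are a single detection.

Coordinates must be planar meters (a projected CRS).  Geographic
latitude/longitude input is rejected rather than converted, because every
distance in the detection model is Euclidean meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrapArray",
    "EncounterData",
    "SessionSet",
    "Dialect",
    "DataValidationError",
    "DuplicateSiteError",
    "CoordinateError",
    "RaggedActivityError",
    "UnknownSiteError",
    "InactiveDetectionError",
    "read_traps",
    "read_encounters",
    "write_traps",
    "write_encounters",
    "collapse_occasions",
    "day_to_occasion",
    "collapse_activity",
    "drop_individuals",
]

SEX_CODES = ("F", "M", "U")


class DataValidationError(ValueError):
    """Base class for input-validation failures."""


class DuplicateSiteError(DataValidationError):
    pass


class CoordinateError(DataValidationError):
    pass


class RaggedActivityError(DataValidationError):
    pass


class UnknownSiteError(DataValidationError):
    pass


class InactiveDetectionError(DataValidationError):
    pass


@dataclass(frozen=True)
class Dialect:
    """File-dialect configuration for trap and encounter tables.

    mode : 'daily' or 'occasion' — whether effort/detection columns are
        per trap night or already collapsed to occasions.
    occasion_length : trap nights per occasion (used only in daily mode).
    delimiter : field separator.
    """

    mode: str = "daily"
    occasion_length: int = 5
    delimiter: str = ","

    def __post_init__(self):
        if self.mode not in ("daily", "occasion"):
            raise DataValidationError(f"unknown dialect mode {self.mode!r}")
        if self.occasion_length < 1:
            raise DataValidationError("occasion_length must be >= 1")


@dataclass
class TrapArray:
    """Camera-trap sites with projected coordinates and an effort mask.

    activity has shape (n_sites, n_occasions) with entries in {0, 1};
    1 means the site was operational during at least one night of the
    occasion.  cell_size records the sampling-grid cell side (design
    metadata, meters); it plays no role in estimation.
    """

    site_id: list
    x: np.ndarray
    y: np.ndarray
    activity: np.ndarray
    cell_size: float | None = None

    def __post_init__(self):
        self.site_id = [str(s) for s in self.site_id]
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.activity = np.asarray(self.activity, dtype=np.int8)
        if self.activity.ndim != 2 or self.activity.shape[0] != len(self.site_id):
            raise DataValidationError(
                f"activity must be (n_sites, n_occasions); got {self.activity.shape}"
            )
        if len(set(self.site_id)) != len(self.site_id):
            seen, dup = set(), None
            for s in self.site_id:
                if s in seen:
                    dup = s
                    break
                seen.add(s)
            raise DuplicateSiteError(f"duplicate site id {dup!r}")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            bad = int(np.flatnonzero(~(np.isfinite(self.x) & np.isfinite(self.y)))[0])
            raise CoordinateError(
                f"non-finite coordinate for site {self.site_id[bad]!r}"
            )
        # planar meters required: coordinates that all fit in [-180, 180] x
        # [-90, 90] are almost certainly geographic and are refused
        if (
            len(self.site_id) > 1
            and np.abs(self.x).max() <= 180.0
            and np.abs(self.y).max() <= 90.0
        ):
            raise CoordinateError(
                "coordinates look like geographic lat/long; supply projected "
                "planar meters"
            )
        if not np.isin(self.activity, (0, 1)).all():
            raise DataValidationError("activity entries must be 0 or 1")
        idle = np.flatnonzero(self.activity.sum(axis=1) == 0)
        if idle.size:
            raise DataValidationError(
                f"site {self.site_id[int(idle[0])]!r} has no active occasion"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    @property
    def n_occasions(self) -> int:
        return self.activity.shape[1]

    @property
    def coords(self) -> np.ndarray:
        """(n_sites, 2) array of x, y in meters."""
        return np.column_stack([self.x, self.y])

    def site_index(self, site) -> int:
        try:
            return self.site_id.index(str(site))
        except ValueError:
            raise UnknownSiteError(f"unknown site id {site!r}") from None

    def collapse(self, occasion_length: int) -> "TrapArray":
        """Collapse a daily activity mask to occasions of L trap nights."""
        return replace(
            self, activity=collapse_activity(self.activity, occasion_length)
        )


@dataclass
class EncounterData:
    """Binary encounter histories for one survey session.

    y has shape (n_individuals, n_sites, n_occasions) with entries in
    {0, 1}; sex holds one of 'F', 'M', 'U' per individual.
    """

    individuals: list
    sex: list
    y: np.ndarray
    session_id: str = "session"

    def __post_init__(self):
        self.individuals = [str(i) for i in self.individuals]
        self.sex = [str(s) for s in self.sex]
        self.y = np.asarray(self.y, dtype=np.int8)
        n = len(self.individuals)
        if self.y.ndim != 3 or self.y.shape[0] != n:
            raise DataValidationError(
                f"y must be (n_individuals, n_sites, n_occasions); got {self.y.shape}"
            )
        if len(self.sex) != n:
            raise DataValidationError("sex must have one entry per individual")
        bad = set(self.sex) - set(SEX_CODES)
        if bad:
            raise DataValidationError(f"invalid sex codes {sorted(bad)}")
        if not np.isin(self.y, (0, 1)).all():
            raise DataValidationError("encounter entries must be 0 or 1")
        if n and (self.y.reshape(n, -1).sum(axis=1) == 0).any():
            i = int(np.flatnonzero(self.y.reshape(n, -1).sum(axis=1) == 0)[0])
            raise DataValidationError(
                f"individual {self.individuals[i]!r} has no detection"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def validate_against(self, traps: TrapArray) -> None:
        """Check dimensions and that detections fall on active site-occasions."""
        if self.y.shape[1:] != traps.activity.shape:
            raise DataValidationError(
                f"encounter array {self.y.shape[1:]} does not match trap "
                f"activity {traps.activity.shape}"
            )
        off = self.y * (1 - traps.activity)[None, :, :]
        if off.any():
            i, j, k = (int(v[0]) for v in np.nonzero(off))
            raise InactiveDetectionError(
                f"detection of {self.individuals[i]!r} at site "
                f"{traps.site_id[j]!r}, occasion {k + 1}, which was inactive"
            )


@dataclass
class SessionSet:
    """Multi-session survey: sessions plus detection-parameter sharing.

    sharing maps each session_id to a sharing-group label: sessions in one
    group are fitted with common detection parameters (p0, sigma) while
    density is always estimated per session.  Omitted sessions get their
    own singleton group.
    """

    sessions: list  # of (TrapArray, EncounterData)
    sharing: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [enc.session_id for _, enc in self.sessions]
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicate session ids")
        for traps, enc in self.sessions:
            enc.validate_against(traps)
        self.sharing = {
            enc.session_id: self.sharing.get(enc.session_id, enc.session_id)
            for _, enc in self.sessions
        }

    @property
    def session_ids(self) -> list:
        return [enc.session_id for _, enc in self.sessions]

    @property
    def groups(self) -> list:
        """Sharing-group labels in first-appearance order."""
        out = []
        for sid in self.session_ids:
            g = self.sharing[sid]
            if g not in out:
                out.append(g)
        return out


def day_to_occasion(day: int, occasion_length: int = 5) -> int:
    """Map a 1-based day index to its 1-based occasion index."""
    if occasion_length < 1:
        raise DataValidationError("occasion_length must be >= 1")
    if day < 1:
        raise DataValidationError("day indices start at 1")
    return (int(day) - 1) // int(occasion_length) + 1


def collapse_activity(daily: np.ndarray, occasion_length: int = 5) -> np.ndarray:
    """Collapse a (sites x days) daily mask to (sites x occasions).

    Occasion k covers days (k-1)*L+1 ... k*L; the number of occasions is
    ceil(days / L), so a trailing short occasion is retained with its true
    days.  A site-occasion is active if at least one of its days is active.
    """
    if occasion_length < 1:
        raise DataValidationError("occasion_length must be >= 1")
    daily = np.asarray(daily)
    n_days = daily.shape[1]
    n_occ = math.ceil(n_days / occasion_length)
    out = np.zeros((daily.shape[0], n_occ), dtype=np.int8)
    for k in range(n_occ):
        sl = daily[:, k * occasion_length : (k + 1) * occasion_length]
        out[:, k] = (sl.sum(axis=1) > 0).astype(np.int8)
    return out


def collapse_occasions(
    daily_records: pd.DataFrame,
    traps: TrapArray,
    occasion_length: int = 5,
    session_id: str | None = None,
    on_inactive: str = "error",
) -> EncounterData:
    """Collapse daily detection records to occasion-level encounter histories.

    daily_records needs columns individual, day, site (optionally sex);
    day indices are 1-based within the session.  traps carries the
    occasion-level activity mask (already collapsed).  Repeated records of
    one individual at one site within one occasion become a single 1.
    """
    recs = daily_records.copy()
    recs["occasion"] = [
        day_to_occasion(d, occasion_length) for d in recs["day"].astype(int)
    ]
    return _records_to_encounters(
        recs, traps, session_id=session_id, on_inactive=on_inactive
    )


def _records_to_encounters(recs, traps, session_id=None, on_inactive="error"):
    if session_id is None:
        session_id = (
            str(recs["session"].iloc[0]) if "session" in recs and len(recs) else "session"
        )
    if len(recs) == 0:
        return EncounterData(
            [], [], np.zeros((0, traps.n_sites, traps.n_occasions)), session_id
        )
    inds: list[str] = []
    sex: dict[str, str] = {}
    rows = []
    for _, r in recs.iterrows():
        ind = str(r["individual"])
        if ind not in sex:
            inds.append(ind)
            sex[ind] = "U"
        sval = r.get("sex", "U")
        if sval is None or pd.isna(sval):
            sval = "U"
        s = str(sval).strip().upper() or "U"
        if s not in SEX_CODES:
            raise DataValidationError(
                f"invalid sex {s!r} for individual {ind!r}"
            )
        if s != "U":
            sex[ind] = s
        j = traps.site_index(r["site"])
        k = int(r["occasion"]) - 1
        if not 0 <= k < traps.n_occasions:
            raise DataValidationError(
                f"occasion {k + 1} outside 1..{traps.n_occasions} "
                f"for individual {ind!r}"
            )
        rows.append((ind, j, k))
    y = np.zeros((len(inds), traps.n_sites, traps.n_occasions), dtype=np.int8)
    pos = {ind: i for i, ind in enumerate(inds)}
    for ind, j, k in rows:
        if traps.activity[j, k] == 0:
            if on_inactive == "drop":
                continue
            raise InactiveDetectionError(
                f"detection of {ind!r} at site {traps.site_id[j]!r}, "
                f"occasion {k + 1}, which was inactive"
            )
        y[pos[ind], j, k] = 1
    keep = y.reshape(len(inds), -1).sum(axis=1) > 0
    inds = [i for i, k_ in zip(inds, keep) if k_]
    return EncounterData(inds, [sex[i] for i in inds], y[keep], session_id)


def read_traps(path, dialect: Dialect = Dialect()) -> TrapArray:
    """Read a trap-deployment CSV: columns site, x, y, then d1..dK (daily
    0/1 flags) or o1..oK (occasion flags), per the dialect."""
    df = pd.read_csv(
        path, sep=dialect.delimiter, dtype={"site": str},
        float_precision="round_trip",
    )
    for col in ("site", "x", "y"):
        if col not in df.columns:
            raise DataValidationError(f"trap file missing column {col!r}")
    prefix = "d" if dialect.mode == "daily" else "o"
    flag_cols = [c for c in df.columns if c not in ("site", "x", "y")]
    bad = [c for c in flag_cols if not (c.startswith(prefix) and c[1:].isdigit())]
    if bad:
        raise DataValidationError(
            f"unexpected activity columns {bad} for dialect mode {dialect.mode!r}"
        )
    flag_cols.sort(key=lambda c: int(c[1:]))
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise CoordinateError(
                f"non-numeric {col!r} in row {row} (site {df['site'].iloc[row]!r})"
            )
        df[col] = vals
    act = df[flag_cols].to_numpy()
    ragged = pd.isna(act)
    if ragged.any():
        r, c = np.argwhere(ragged)[0]
        raise RaggedActivityError(
            f"missing activity flag at row {int(r)}, column {flag_cols[int(c)]!r}"
        )
    traps = TrapArray(
        list(df["site"]), df["x"].to_numpy(), df["y"].to_numpy(), act.astype(np.int8)
    )
    if dialect.mode == "daily":
        traps = traps.collapse(dialect.occasion_length)
    return traps


def read_encounters(
    path,
    traps: TrapArray,
    dialect: Dialect = Dialect(),
    session: str | None = None,
    on_inactive: str = "error",
) -> EncounterData:
    """Read an encounter CSV (session, individual, day|occasion, site, sex).

    Sites must exist in the TrapArray; detections on inactive site-occasions
    raise InactiveDetectionError unless on_inactive='drop'.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    if len(df) == 0:
        return EncounterData(
            [], [], np.zeros((0, traps.n_sites, traps.n_occasions)),
            session or "session",
        )
    if "session" in df.columns:
        if session is not None:
            df = df[df["session"] == str(session)]
        elif df["session"].nunique() > 1:
            raise DataValidationError(
                "file holds multiple sessions; pass session= to select one"
            )
    sid = session or (str(df["session"].iloc[0]) if "session" in df else "session")
    if dialect.mode == "daily":
        if "day" not in df.columns:
            raise DataValidationError("daily dialect requires a 'day' column")
        df = df.assign(day=df["day"].astype(int))
        return collapse_occasions(
            df, traps, dialect.occasion_length, session_id=sid,
            on_inactive=on_inactive,
        )
    if "occasion" not in df.columns:
        raise DataValidationError("occasion dialect requires an 'occasion' column")
    df = df.assign(occasion=df["occasion"].astype(int))
    return _records_to_encounters(df, traps, session_id=sid, on_inactive=on_inactive)


def write_traps(traps: TrapArray, path) -> None:
    """Write a TrapArray as an occasion-dialect CSV (o1..oK flags)."""
    cols = {"site": traps.site_id, "x": traps.x, "y": traps.y}
    for k in range(traps.n_occasions):
        cols[f"o{k + 1}"] = traps.activity[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_encounters(enc: EncounterData, traps: TrapArray, path) -> None:
    """Write encounters as an occasion-dialect CSV (one row per detection)."""
    rows = []
    for i, j, k in zip(*np.nonzero(enc.y)):
        rows.append(
            {
                "session": enc.session_id,
                "individual": enc.individuals[i],
                "occasion": k + 1,
                "site": traps.site_id[j],
                "sex": enc.sex[i],
            }
        )
    pd.DataFrame(
        rows, columns=["session", "individual", "occasion", "site", "sex"]
    ).to_csv(path, index=False)


def drop_individuals(enc: EncounterData, drop: list) -> EncounterData:
    """Remove listed individuals (e.g. unconfirmed identifications or
    juveniles flagged upstream) from an EncounterData."""
    drop = {str(d) for d in drop}
    keep = [i for i, ind in enumerate(enc.individuals) if ind not in drop]
    return EncounterData(
        [enc.individuals[i] for i in keep],
        [enc.sex[i] for i in keep],
        enc.y[keep],
        enc.session_id,
    )
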