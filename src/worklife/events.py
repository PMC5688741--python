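"""Long-format (counting-process) event histories and risk-set tables.

An event history is a table with one row per subject-episode: the subject
identifier, a half-open age interval ``[entry_age, exit_age)`` spent in
``from_state``, the destination ``to_state`` reached at ``exit_age`` (or the
reserved marker :data:`CENSORED`), episode-constant covariate values and an
optional nonnegative weight.  Age in years is the time scale throughout.

An event occurs *at* ``exit_age``; a subject is at risk in state ``h`` at age
``t`` iff ``entry_age < t <= exit_age`` for an episode in ``h``.  This matches
register date arithmetic and makes risk-set membership unambiguous at event
ages.  Tied event ages are allowed and aggregate (Breslow-style downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import StateSpace

#: reserved destination marker for right-censored episodes
CENSORED = "CENSORED"

#: canonical column names of the long format
CORE_COLUMNS = ["subject_id", "entry_age", "exit_age", "from_state", "to_state"]


class EventHistoryError(ValueError):
    """Structural defect in an event-history table (names subject and row)."""


@dataclass
class EpisodeRecord:
    """One counting-process row: subject, [entry, exit), origin, destination."""

    subject_id: object
    entry_age: float
    exit_age: float
    from_state: str
    to_state: str = CENSORED
    covariates: dict[str, float] = field(default_factory=dict)
    weight: float = 1.0


def episodes_to_frame(records: list[EpisodeRecord]) -> pd.DataFrame:
    """Convert a list of :class:`EpisodeRecord` to the canonical DataFrame."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "entry_age": r.entry_age,
            "exit_age": r.exit_age,
            "from_state": r.from_state,
            "to_state": r.to_state,
            "weight": r.weight,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_episodes(df: pd.DataFrame) -> list[EpisodeRecord]:
    cov_cols = covariate_columns(df)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            EpisodeRecord(
                subject_id=d["subject_id"],
                entry_age=float(d["entry_age"]),
                exit_age=float(d["exit_age"]),
                from_state=d["from_state"],
                to_state=d["to_state"],
                covariates={c: d[c] for c in cov_cols},
                weight=float(d.get("weight", 1.0)),
            )
        )
    return out


def covariate_columns(df: pd.DataFrame) -> list[str]:
    """Columns of ``df`` that are neither core columns nor the weight."""
    skip = set(CORE_COLUMNS) | {"weight"}
    return [c for c in df.columns if c not in skip]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_episodes(
    df: pd.DataFrame,
    space: StateSpace,
    censor_at_pension_age: bool = True,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Validate and normalize an event-history table.

    Checks, per row: ``entry_age < exit_age``, known state labels, no episode
    starting in an absorbing state.  Per subject: episodes non-overlapping,
    time-ordered and chained (each episode starts in the state the previous
    one transitioned to).  Episodes extending beyond ``space.pension_age`` are
    truncated there and administratively censored.

    Returns a sorted copy with a ``weight`` column and ``to_state`` normalized
    (NaN / empty string -> :data:`CENSORED`).

    Raises
    ------
    EventHistoryError
        Naming the offending subject and row.
    """
    df = df.copy()
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise EventHistoryError(f"missing required columns: {missing}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["entry_age"] = df["entry_age"].astype(float)
    df["exit_age"] = df["exit_age"].astype(float)
    df["to_state"] = df["to_state"].where(df["to_state"].notna(), CENSORED)
    df.loc[df["to_state"].astype(str).str.strip() == "", "to_state"] = CENSORED

    if len(df) == 0:
        return df

    if (df["weight"] < 0).any():
        i = int(df.index[df["weight"] < 0][0])
        raise EventHistoryError(f"row {i}: negative weight")

    known = set(space.states)
    for col in ("from_state", "to_state"):
        bad = ~df[col].isin(known | {CENSORED})
        if bad.any():
            i = df.index[bad][0]
            raise EventHistoryError(
                f"row {i} (subject {df.loc[i, 'subject_id']}): "
                f"unknown state label {df.loc[i, col]!r} in {col}"
            )
    bad = df["from_state"].eq(CENSORED)
    if bad.any():
        i = df.index[bad][0]
        raise EventHistoryError(f"row {i}: from_state cannot be {CENSORED}")
    for s in space.absorbing_states:
        bad = df["from_state"].eq(s)
        if bad.any():
            i = df.index[bad][0]
            raise EventHistoryError(
                f"row {i} (subject {df.loc[i, 'subject_id']}): "
                f"episode starts in absorbing state {s!r}"
            )

    # administrative censoring at pension age
    if censor_at_pension_age:
        tp = space.pension_age
        drop = df["entry_age"] >= tp - atol
        if drop.any():
            df = df[~drop].copy()
        over = df["exit_age"] > tp
        df.loc[over, "exit_age"] = tp
        df.loc[over, "to_state"] = CENSORED

    bad = ~(df["entry_age"] < df["exit_age"])
    if bad.any():
        i = df.index[bad][0]
        raise EventHistoryError(
            f"row {i} (subject {df.loc[i, 'subject_id']}): exit_age <= entry_age"
        )

    df = df.sort_values(["subject_id", "entry_age"], kind="stable").reset_index(
        drop=True
    )
    for sid, g in df.groupby("subject_id", sort=False):
        entries = g["entry_age"].to_numpy()
        exits = g["exit_age"].to_numpy()
        if (entries[1:] < exits[:-1] - atol).any():
            raise EventHistoryError(f"subject {sid}: overlapping episodes")
        to_prev = g["to_state"].to_numpy()[:-1]
        from_next = g["from_state"].to_numpy()[1:]
        for k, (t0, f1) in enumerate(zip(to_prev, from_next)):
            if t0 == CENSORED:
                raise EventHistoryError(
                    f"subject {sid}: episode follows a censored episode"
                )
            if t0 != f1:
                raise EventHistoryError(
                    f"subject {sid}: broken chain (episode {k} ends in {t0!r}, "
                    f"episode {k + 1} starts in {f1!r})"
                )
    return df


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_event_history(
    path,
    space: StateSpace | None = None,
    schema: dict[str, str] | None = None,
    statespace_path=None,
    validate: bool = True,
) -> tuple[pd.DataFrame, StateSpace]:
    """Read a long-format event-history CSV (optionally with a YAML sidecar).

    Parameters
    ----------
    path : path-like
        Comma-delimited text, header row, one episode per row.
    space : StateSpace, optional
        Supplied state space; otherwise read from ``statespace_path``.
    schema : dict, optional
        Mapping canonical name -> column name in the file, for files whose
        headers differ from the canonical layout.
    statespace_path : path-like, optional
        YAML sidecar declaring the state space.

    Returns
    -------
    (DataFrame, StateSpace)
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    if space is None:
        if statespace_path is None:
            raise ValueError("supply either `space` or `statespace_path`")
        space = StateSpace.from_yaml(statespace_path)
    if len(df) == 0:
        df = pd.DataFrame(columns=CORE_COLUMNS + ["weight"])
    if validate:
        df = validate_episodes(df, space)
    return df, space


def write_event_history(df: pd.DataFrame, path, space: StateSpace | None = None,
                        statespace_path=None) -> None:
    df.to_csv(path, index=False)
    if space is not None and statespace_path is not None:
        space.to_yaml(statespace_path)


# ---------------------------------------------------------------------------
# risk sets
# ---------------------------------------------------------------------------

@dataclass
class RiskSetTable:
    """Event counts and at-risk counts on the grid of distinct event ages.

    Attributes
    ----------
    ages : ndarray, shape (K,)
        Strictly increasing distinct event ages (any transition).
    d : DataFrame, shape (K, n_transitions)
        Weighted event count per transition at each age (columns keyed by
        :attr:`Transition.name`); 0 where the transition has no event.
    n : DataFrame, shape (K, n_states)
        Weighted at-risk count per *state* just before each age.  Combined
        transitions use the sum over their origin states.
    space : StateSpace
    """

    ages: np.ndarray
    d: pd.DataFrame
    n: pd.DataFrame
    space: StateSpace

    def n_for(self, origins: tuple[str, ...]) -> np.ndarray:
        """At-risk count of a (possibly pooled) origin set at every age."""
        return self.n[list(origins)].sum(axis=1).to_numpy()

    def event_ages(self, name: str) -> np.ndarray:
        """Ages at which transition ``name`` has at least one event."""
        col = self.d[name].to_numpy()
        return self.ages[col > 0]


def _at_risk_counts(entries, exits, weights, ages):
    """Weighted count with entry < t <= exit at each t in `ages` (sorted)."""
    # [exit >= t] - [entry >= t] == [entry < t <= exit]  (since entry < exit)
    o = np.argsort(entries)
    ent, went = entries[o], np.concatenate([[0.0], np.cumsum(weights[o])])
    o = np.argsort(exits)
    ex, wex = exits[o], np.concatenate([[0.0], np.cumsum(weights[o])])
    total = went[-1]
    n_entry_ge = total - went[np.searchsorted(ent, ages, side="left")]
    n_exit_ge = total - wex[np.searchsorted(ex, ages, side="left")]
    return n_exit_ge - n_entry_ge


def build_risk_sets(df: pd.DataFrame, space: StateSpace) -> RiskSetTable:
    """Tabulate weighted event counts d and at-risk counts n at event ages.

    ``d`` for a combined transition pools events from all origin states;
    ``n`` is tabulated per state and pooled on demand (union risk set).
    """
    if "weight" not in df.columns:
        df = df.assign(weight=1.0)
    w = df["weight"].to_numpy(float)
    entry = df["entry_age"].to_numpy(float)
    exit_ = df["exit_age"].to_numpy(float)
    from_s = df["from_state"].to_numpy()
    to_s = df["to_state"].to_numpy()

    # distinct event ages over the transitions of the space
    is_event = np.zeros(len(df), bool)
    trans_masks = {}
    for tr in space.transitions:
        m = np.isin(from_s, tr.origins) & (to_s == tr.to_state)
        trans_masks[tr.name] = m
        is_event |= m
    ages = np.unique(exit_[is_event])

    d = pd.DataFrame(0.0, index=ages, columns=[t.name for t in space.transitions])
    for tr in space.transitions:
        m = trans_masks[tr.name]
        if m.any():
            s = pd.Series(w[m]).groupby(exit_[m]).sum()
            d.loc[s.index, tr.name] = s.to_numpy()

    n = pd.DataFrame(0.0, index=ages, columns=space.state_order)
    for state in space.state_order:
        m = from_s == state
        if m.any() and len(ages):
            n[state] = _at_risk_counts(entry[m], exit_[m], w[m], ages)

    return RiskSetTable(ages=ages, d=d, n=n, space=space)
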