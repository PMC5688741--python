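"""State spaces for multi-state labor-market models.

A :class:`StateSpace` declares the labeled states of a multi-state model, the
set of transitions whose hazards are estimated, which states are absorbing,
and which states count toward worklife expectancy (WLE).  The default instance
(:func:`danish_labor_market`) is the five-primary-state labor-market model:
work (W), sickness absence (S), unemployment (U), disability pension (D) and
voluntary early-retirement pension (E), with auxiliary temporary-out (TO) and
Death states.  D, E and Death are absorbing; W, S, U and TO are "transdurable"
(recurrent entry and exit is possible); WLE counts time in W, S and U.

Transitions may pool several origin states into one risk set (a *combined*
transition, e.g. ``{W,S,U} -> D``), used when destination-specific events are
too sparse to estimate origin-specific hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: role labels
TRANSDURABLE = "transdurable"
ABSORBING = "absorbing"
AUXILIARY = "auxiliary"

_ROLES = (TRANSDURABLE, ABSORBING, AUXILIARY)


@dataclass(frozen=True)
class Transition:
    """A transition whose hazard is estimated on a (possibly pooled) risk set.

    ``origins`` is a tuple of one or more origin-state labels; a tuple of
    length > 1 declares a combined transition estimated on the union risk set.
    """

    origins: tuple[str, ...]
    to_state: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "origins", tuple(self.origins))

    @property
    def combined(self) -> bool:
        return len(self.origins) > 1

    @property
    def name(self) -> str:
        return "+".join(self.origins) + "->" + self.to_state

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class StateSpace:
    """Labeled state set, transition set and WLE bookkeeping.

    Parameters
    ----------
    states : dict
        Mapping label -> role, role in ``{"transdurable", "absorbing",
        "auxiliary"}``.
    transitions : list of Transition
        Ordered transitions; order fixes column layout in exports.
    wle_states : set of str
        Transdurable states whose occupation time counts toward WLE.
    pension_age : float
        Administrative censoring age (years); horizon of every expectancy.
    absorbing_auxiliary : set of str
        Auxiliary states that admit no exit (e.g. Death).
    """

    states: dict[str, str]
    transitions: list[Transition]
    wle_states: set[str]
    pension_age: float = 65.0
    absorbing_auxiliary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.transitions = [
            t if isinstance(t, Transition) else Transition(tuple(t[0]), t[1])
            for t in self.transitions
        ]
        self.wle_states = set(self.wle_states)
        self.absorbing_auxiliary = set(self.absorbing_auxiliary)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        for s, role in self.states.items():
            if role not in _ROLES:
                raise ValueError(f"state {s!r}: unknown role {role!r}")
        unknown = self.absorbing_auxiliary - set(self.states)
        if unknown:
            raise ValueError(f"absorbing_auxiliary not in states: {unknown}")
        for tr in self.transitions:
            for o in tr.origins:
                if o not in self.states:
                    raise ValueError(f"transition {tr}: unknown origin {o!r}")
                if self.is_absorbing(o):
                    raise ValueError(
                        f"transition {tr}: absorbing state {o!r} cannot be an origin"
                    )
            if tr.to_state not in self.states:
                raise ValueError(f"transition {tr}: unknown destination")
            if tr.combined:
                n_trans = sum(
                    1 for o in tr.origins if self.states[o] == TRANSDURABLE
                )
                if n_trans < 2:
                    raise ValueError(
                        f"combined transition {tr} needs >= 2 transdurable origins"
                    )
        bad = self.wle_states - self.transdurable_states
        if bad:
            raise ValueError(f"wle_states must be transdurable: {bad}")

    # -- convenience views -------------------------------------------------
    @property
    def state_order(self) -> list[str]:
        return list(self.states)

    @property
    def transdurable_states(self) -> set[str]:
        return {s for s, r in self.states.items() if r == TRANSDURABLE}

    def is_absorbing(self, state: str) -> bool:
        return self.states[state] == ABSORBING or state in self.absorbing_auxiliary

    @property
    def absorbing_states(self) -> set[str]:
        return {s for s in self.states if self.is_absorbing(s)}

    def index(self, state: str) -> int:
        return self.state_order.index(state)

    def transition_by_name(self, name: str) -> Transition:
        for tr in self.transitions:
            if tr.name == name:
                return tr
        raise KeyError(name)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": dict(self.states),
            "absorbing_auxiliary": sorted(self.absorbing_auxiliary),
            "transitions": [
                {"from": list(t.origins), "to": t.to_state} for t in self.transitions
            ],
            "wle_states": sorted(self.wle_states),
            "pension_age": float(self.pension_age),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpace":
        return cls(
            states=dict(d["states"]),
            transitions=[
                Transition(tuple(t["from"]), t["to"]) for t in d["transitions"]
            ],
            wle_states=set(d.get("wle_states", ())),
            pension_age=float(d.get("pension_age", 65.0)),
            absorbing_auxiliary=set(d.get("absorbing_auxiliary", ())),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StateSpace":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def danish_labor_market(
    erp: bool = True,
    pension_age: float = 65.0,
    death: bool = False,
) -> StateSpace:
    """The default five-primary-state labor-market model.

    Parameters
    ----------
    erp : bool
        Include the voluntary early-retirement pension state E and the pooled
        ``{W,S,U} -> E`` transition.  Non-members of the scheme are modeled on
        the reduced four-primary-state space (W, S, U, D).
    death : bool
        Add a pooled ``{W,S,U} -> Death`` transition.  The Death state is
        always present as an absorbing auxiliary state; without this flag it
        simply has no estimated transition.
    """
    states = {"W": TRANSDURABLE, "S": TRANSDURABLE, "U": TRANSDURABLE}
    states["D"] = ABSORBING
    if erp:
        states["E"] = ABSORBING
    states["TO"] = AUXILIARY
    states["Death"] = AUXILIARY
    core = ("W", "S", "U")
    transitions = [
        Transition(("W",), "S"),
        Transition(("W",), "U"),
        Transition(("S",), "W"),
        Transition(("S",), "U"),
        Transition(("U",), "W"),
        Transition(("U",), "S"),
        Transition(core, "D"),
    ]
    if erp:
        transitions.append(Transition(core, "E"))
    if death:
        transitions.append(Transition(core, "Death"))
    return StateSpace(
        states=states,
        transitions=transitions,
        wle_states={"W", "S", "U"},
        pension_age=pension_age,
        absorbing_auxiliary={"Death"},
    )
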