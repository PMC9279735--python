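"""Structure-specific dosimetric endpoints and threshold-crossing detection.

Each monitored dosimetric parameter carries a *warning* level ``DE_0`` and an
*adaptation* level.  Targets are lower-bounded on coverage (V95 warning 95%,
adaptation 93%) and upper-bounded on hotspot (110% of prescription at both
levels); OARs are upper-bounded, with the adaptation level ``DE_10`` set to
exactly 1.10 x DE_0 wherever a +10% deviation endpoint applies, and equal to
the planning goal where no relaxed level exists (e.g. mandible D1cc).

Parotid glands are special-cased: a spared gland whose *planned* Dmean met
the <20 Gy goal is monitored against 20 Gy; if the plan could not spare it
below 20 Gy but stayed below 21 Gy, against 21 Gy; a spared contralateral
gland planned below 26 Gy is monitored against 26 Gy.

Violations use strict inequalities (a value exactly at a threshold does not
violate), so boundary cases are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

DIRECTIONS = ("lower_bound", "upper_bound")
LEVELS = ("warning", "adaptation")
PAROTID_ROLES = ("spared", "contralateral_spared")


@dataclass
class EndpointSpec:
    """A monitored dosimetric parameter with warning and adaptation levels."""

    structure: str
    metric: str                # one of dvh.METRIC_KINDS
    direction: str             # lower_bound (targets) / upper_bound (OARs)
    warning_level: float       # DE_0 (% for V95/hotspot, Gy otherwise)
    adaptation_level: float    # DE_10 for relative OAR endpoints
    reference: float | None = None  # Rx (Gy) for V95/hotspot metrics

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "upper_bound" and self.adaptation_level < self.warning_level:
            raise ValueError("adaptation level must be >= warning for upper bounds")
        if self.direction == "lower_bound" and self.adaptation_level > self.warning_level:
            raise ValueError("adaptation level must be <= warning for lower bounds")

    def level(self, which: str) -> float:
        return self.warning_level if which == "warning" else self.adaptation_level

    def violates(self, value: float, which: str = "warning") -> bool:
        threshold = self.level(which)
        if self.direction == "lower_bound":
            return value < threshold
        return value > threshold


@dataclass
class ViolationEvent:
    """First strict crossing of an endpoint level by a DP_sum trajectory."""

    structure: str
    metric: str
    level: str                  # warning / adaptation
    crossing_fraction: int      # Fx, 1-based
    value_at_crossing: float
    cumulative_dose_gy: float | None = None  # Fx x dose-per-fraction
    at_eot: bool = False        # still violating at the final processed fraction


def resolve_parotid_endpoint(
    planned_dmean: float, role: str = "spared", structure: str = "parotid"
) -> EndpointSpec | None:
    """Map a parotid's planned Dmean to its monitoring endpoint.

    Returns ``None`` (excluded from monitoring, logged) when the planned
    Dmean falls outside every rule range.
    """
    if role not in PAROTID_ROLES:
        raise ValueError(f"unknown parotid role {role!r}")
    if role == "spared":
        if planned_dmean < 20.0:
            de0 = 20.0
        elif planned_dmean < 21.0:
            de0 = 21.0
        else:
            log.info(
                "parotid %s (planned Dmean %.2f Gy) outside spared-gland rule "
                "ranges; excluded from monitoring", structure, planned_dmean,
            )
            return None
    else:
        if planned_dmean < 26.0:
            de0 = 26.0
        else:
            log.info(
                "contralateral parotid %s (planned Dmean %.2f Gy) >= 26 Gy; "
                "excluded from monitoring", structure, planned_dmean,
            )
            return None
    return EndpointSpec(
        structure=structure,
        metric="Dmean",
        direction="upper_bound",
        warning_level=de0,
        adaptation_level=round(1.10 * de0, 10),
    )


#: Default OAR rule table.  ``relative`` endpoints get DE_10 = 1.10 x goal;
#: ``goal`` endpoints keep warning = adaptation = planning goal; ``hotspot``
#: endpoints bound Dmax at 110% of the (highest) prescription at both levels.
DEFAULT_OAR_RULES: dict[str, dict] = {
    "spinal_cord": {"metric": "Dmax", "mode": "relative", "goal": 45.0},
    "brainstem": {"metric": "Dmax", "mode": "relative", "goal": 45.0},
    "oral_cavity": {"metric": "Dmax", "mode": "hotspot"},
    "cervical_esophagus": {"metric": "Dmax", "mode": "hotspot"},
    "larynx": {"metric": "Dmax", "mode": "hotspot"},
    "mandible": {"metric": "D1cc", "mode": "goal", "goal": 72.0},
    "cochlea": {"metric": "Dmean", "mode": "relative", "goal": 35.0},
    "brachial_plexus": {"metric": "Dmax", "mode": "goal", "goal": 66.0},
}

VALID_MODES = ("relative", "goal", "hotspot", "parotid")


def build_endpoint_set(
    plan, plan_metrics: dict[str, dict[str, float]] | None = None,
    config: dict[str, dict] | None = None,
) -> list[EndpointSpec]:
    """Build the monitored endpoint set for a plan.

    Every target gets a V95 endpoint (95% / 93%) and a hotspot endpoint
    (110% of its own SIB prescription).  OAR rules come from ``config``
    (falling back to :data:`DEFAULT_OAR_RULES` by structure name); parotid
    structures use ``mode: parotid`` with a ``role`` and are resolved from
    their *planned* Dmean in ``plan_metrics``.
    """
    config = dict(config or {})
    plan_metrics = plan_metrics or {}
    specs: list[EndpointSpec] = []
    for name, rule in config.items():
        mode = rule.get("mode")
        if mode not in VALID_MODES:
            raise ValueError(f"endpoint config for {name!r}: unknown mode {mode!r}")
        metric = rule.get("metric", "Dmean" if mode == "parotid" else None)
        if mode != "parotid" and metric not in ("V95", "Dmean", "Dmax", "D1cc", "hotspot"):
            raise ValueError(f"endpoint config for {name!r}: unknown metric {metric!r}")

    targets = [s for s in plan.structures if s.role == "target"]
    for s in plan.structures:
        if s.role == "target":
            rx = float(s.prescription)
            # In a SIB plan a lower-level target encloses the boost plateau,
            # so its hotspot is judged against the highest prescription among
            # overlapping targets, not its own level.
            hot_rx = max(
                (float(t.prescription) for t in targets
                 if np.any(t.mask & s.mask)),
                default=rx,
            )
            specs.append(
                EndpointSpec(s.name, "V95", "lower_bound", 95.0, 93.0, reference=rx)
            )
            specs.append(
                EndpointSpec(
                    s.name, "hotspot", "upper_bound", 110.0, 110.0, reference=hot_rx
                )
            )
        elif s.role == "oar":
            rule = config.get(s.name) or _default_rule(s.name)
            if rule is None:
                continue
            mode = rule["mode"]
            if mode == "parotid":
                planned = plan_metrics.get(s.name, {}).get("Dmean")
                if planned is None:
                    raise ValueError(
                        f"parotid endpoint for {s.name!r} needs the planned Dmean"
                    )
                spec = resolve_parotid_endpoint(
                    planned, rule.get("role", "spared"), structure=s.name
                )
                if spec is not None:
                    specs.append(spec)
            elif mode == "relative":
                goal = float(rule["goal"])
                specs.append(
                    EndpointSpec(s.name, rule["metric"], "upper_bound",
                                 goal, round(1.10 * goal, 10))
                )
            elif mode == "goal":
                goal = float(rule["goal"])
                specs.append(
                    EndpointSpec(s.name, rule["metric"], "upper_bound", goal, goal)
                )
            elif mode == "hotspot":
                rx = plan.max_prescription
                specs.append(
                    EndpointSpec(s.name, "Dmax", "upper_bound",
                                 1.10 * rx, 1.10 * rx, reference=rx)
                )
    return specs


def _default_rule(name: str) -> dict | None:
    key = name.lower()
    if "parotid" in key:
        return {"mode": "parotid", "role": "spared"}
    for rule_name, rule in DEFAULT_OAR_RULES.items():
        if rule_name in key:
            return rule
    return None


def detect_crossings(
    trajectory: np.ndarray,
    spec: EndpointSpec,
    dose_per_fraction: float | None = None,
) -> list[ViolationEvent]:
    """Locate the first strict crossing of each endpoint level.

    ``trajectory`` holds DP_sum values for fractions 1..k in order.  For each
    level the crossing fraction Fx is the smallest fraction whose value
    strictly violates it; the event's ``at_eot`` flag records whether the
    final fraction still violates.  Trajectories may cross and recede — the
    first crossing is still reported.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.size == 0:
        raise ValueError("empty DP trajectory")
    events = []
    for level in LEVELS:
        violating = np.array([spec.violates(v, level) for v in trajectory])
        if not violating.any():
            continue
        fx = int(np.argmax(violating)) + 1
        events.append(
            ViolationEvent(
                structure=spec.structure,
                metric=spec.metric,
                level=level,
                crossing_fraction=fx,
                value_at_crossing=float(trajectory[fx - 1]),
                cumulative_dose_gy=(
                    None if dose_per_fraction is None else fx * dose_per_fraction
                ),
                at_eot=bool(violating[-1]),
            )
        )
    return events
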