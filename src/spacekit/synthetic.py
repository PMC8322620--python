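"""Synthetic tracking + event data with known ground truth.

The simulator emulates the structure of professional tracking feeds: 22
players plus the ball at 25 Hz on a 105 x 68 m pitch, pass/shot event
logs, and per-player kinematic limits, with three planted laws that the
fitting modules are expected to recover:

* a distance -> pass-duration law Delta = alpha + beta * d**gamma + noise,
* defender positioning that is a fixed affine function of the ball
  position (projected into the defending half) plus isotropic noise, so
  the defensive-influence surface is learnable from (ball, point) pairs,
* per-player "skill" multipliers that scale how far a pass receiver
  detaches from the nearest defender before receiving, so space-generation
  rankings are recoverable.

Positional noise enters through the acceleration channel and the speed,
acceleration and turn-rate caps are applied afterwards, so every kinematic
limit holds exactly frame by frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .movement import HORIZONS, VELOCITY_BINS, Triplet, extract_triplets
from .pitch import (
    BALL_ID,
    PassEvent,
    Pitch,
    ShotEvent,
    TrackingSequence,
)

__all__ = [
    "KinematicProfile",
    "PassLaw",
    "OutcomeLaw",
    "ScenarioConfig",
    "simulate_match",
    "simulate_triplet_corpus",
    "TripletCorpus",
    "defender_rule",
]


@dataclass(frozen=True)
class KinematicProfile:
    """Hard per-player movement limits, enforced at every frame."""

    player_id: str = "player"
    max_speed: float = 8.0       # m/s
    max_accel: float = 6.0       # m/s^2
    turn_rate_cap: float = 2.0 * math.pi  # rad/s

    def __post_init__(self):
        if min(self.max_speed, self.max_accel, self.turn_rate_cap) <= 0:
            raise ValueError("all kinematic caps must be positive")


@dataclass(frozen=True)
class PassLaw:
    """Planted distance -> duration law Delta = alpha + beta * d**gamma + eps."""

    alpha: float = 0.5
    beta: float = 0.045
    gamma: float = 1.0
    noise_sd: float = 0.05

    def duration(self, d: float, rng: np.random.Generator) -> float:
        eps = rng.normal(0.0, self.noise_sd) if self.noise_sd > 0 else 0.0
        return max(self.alpha + self.beta * d ** self.gamma + eps, 0.1)


@dataclass(frozen=True)
class OutcomeLaw:
    """P(success) = logistic(a + b * openness proxy at the final pass
    destination); the proxy is tanh(nearest-defender distance / 10 m)."""

    a: float = -1.5
    b: float = 3.0

    def p_success(self, proxy: float) -> float:
        return 1.0 / (1.0 + math.exp(-(self.a + self.b * proxy)))


# Shared affine defender rule: target_j = base_j + M @ ball, projected into
# the defending half.  M is common to all defenders; bases come from a
# formation template.
_DEF_M = np.array([[0.35, 0.0], [0.0, 0.45]])


def defender_rule(base: np.ndarray, ball: np.ndarray, pitch: Pitch) -> np.ndarray:
    """Deterministic affine defender target for a given ball position.

    Defenders protect the +x goal: targets are clipped into the defending
    half (x in [2, 50.5], y within the pitch)."""
    t = np.asarray(base, dtype=float) + _DEF_M @ np.asarray(ball, dtype=float)
    return np.array([
        np.clip(t[0], 2.0, pitch.length / 2.0 - 2.0),
        np.clip(t[1], -pitch.width / 2.0 + 2.0, pitch.width / 2.0 - 2.0),
    ])


def _formation_bases(n: int, x_center: float, pitch: Pitch) -> np.ndarray:
    """Spread n outfield players over lines around ``x_center``."""
    bases = []
    lines = max(1, int(round(n / 4)))
    per_line = int(math.ceil(n / lines))
    for i in range(n):
        line, slot = divmod(i, per_line)
        x = x_center + 9.0 * (line - (lines - 1) / 2.0)
        y = (slot - (per_line - 1) / 2.0) * (pitch.width - 16.0) / max(per_line - 1, 1)
        bases.append((x, y))
    return np.asarray(bases)


@dataclass
class ScenarioConfig:
    """Everything that defines one synthetic match; same seed, same bytes."""

    seed: int = 0
    n_players: int = 11           # per team, including goalkeeper if enabled
    duration: float = 120.0       # s
    frame_rate: float = 25.0
    pass_law: PassLaw = field(default_factory=PassLaw)
    outcome_law: OutcomeLaw = field(default_factory=OutcomeLaw)
    skill: dict[str, float] = field(default_factory=dict)  # per-player multiplier
    include_goalkeeper: bool = True
    profile: KinematicProfile = field(default_factory=KinematicProfile)
    defender_noise_sd: float = 0.5   # m, isotropic noise on defender targets
    accel_noise_sd: float = 0.8      # m/s^2
    hold_range: tuple[float, float] = (0.8, 2.0)  # s carrier holds the ball
    lead_time: float = 1.0           # s receiver runs free before the pass
    passes_per_possession: tuple[int, int] = (3, 6)
    pitch: Pitch = field(default_factory=Pitch)

    def player_ids(self, team: str) -> list[str]:
        return [f"{team}{i + 1}" for i in range(self.n_players)]

    def skill_of(self, pid: str) -> float:
        return float(self.skill.get(pid, 1.0))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "n_players": self.n_players,
            "duration": self.duration, "frame_rate": self.frame_rate,
            "pass_law": vars(self.pass_law), "outcome_law": vars(self.outcome_law),
            "skill": dict(self.skill),
            "profile": {
                "max_speed": self.profile.max_speed,
                "max_accel": self.profile.max_accel,
                "turn_rate_cap": self.profile.turn_rate_cap,
            },
            "defender_noise_sd": self.defender_noise_sd,
        }


def _kinematic_step(
    pos: np.ndarray,
    vel: np.ndarray,
    targets: np.ndarray,
    profile: KinematicProfile,
    dt: float,
    rng: np.random.Generator,
    accel_noise_sd: float,
    target_speed: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One capped-kinematics integration step for all players at once.

    Desired velocity points at the target with the given cruise speed
    (slowing near the target); acceleration (incl. noise) is capped, then
    the turn rate, then the speed, so the caps hold exactly.
    """
    to_t = targets - pos
    dist = np.linalg.norm(to_t, axis=1)
    safe = np.maximum(dist, 1e-9)
    cruise = np.minimum(target_speed, dist / (4 * dt))  # brake near target
    desired = to_t / safe[:, None] * cruise[:, None]
    acc = (desired - vel) / (6 * dt)
    if accel_noise_sd > 0:
        acc = acc + rng.normal(0.0, accel_noise_sd, size=acc.shape)
    a_norm = np.linalg.norm(acc, axis=1)
    over = a_norm > profile.max_accel
    acc[over] *= (profile.max_accel / a_norm[over])[:, None]
    new_vel = vel + acc * dt

    # turn-rate cap: limit the change of the velocity direction per frame
    sp_old = np.linalg.norm(vel, axis=1)
    sp_new = np.linalg.norm(new_vel, axis=1)
    moving = (sp_old > 0.5) & (sp_new > 1e-9)
    if np.any(moving):
        max_turn = profile.turn_rate_cap * dt
        ang_old = np.arctan2(vel[moving, 1], vel[moving, 0])
        ang_new = np.arctan2(new_vel[moving, 1], new_vel[moving, 0])
        dang = np.arctan2(np.sin(ang_new - ang_old), np.cos(ang_new - ang_old))
        clipped = np.clip(dang, -max_turn, max_turn)
        ang = ang_old + clipped
        new_vel[moving] = np.column_stack([np.cos(ang), np.sin(ang)]) * sp_new[moving, None]

    # speed cap
    sp = np.linalg.norm(new_vel, axis=1)
    fast = sp > profile.max_speed
    new_vel[fast] *= (profile.max_speed / sp[fast])[:, None]
    new_pos = pos + new_vel * dt
    return new_pos, new_vel


def simulate_match(config: ScenarioConfig):
    """Run one synthetic match; returns ``(TrackingSequence, events)``.

    Team A attacks toward +x and circulates the ball; team B defends by
    the planted affine rule.  Pass durations follow the planted pass law,
    and possessions end with a shot with probability given by the planted
    outcome law applied to the receiver's openness.
    """
    rng = np.random.default_rng(config.seed)
    pitch = config.pitch
    dt = 1.0 / config.frame_rate
    n_frames = int(round(config.duration * config.frame_rate)) + 1
    prof = config.profile

    ids_a = config.player_ids("A")
    ids_b = config.player_ids("B")
    all_ids = ids_a + ids_b
    n_tot = len(all_ids)
    gk = {ids_a[0], ids_b[0]} if config.include_goalkeeper else set()
    roles = ["goalkeeper" if pid in gk else "field" for pid in all_ids]
    idx = {pid: i for i, pid in enumerate(all_ids)}
    a_field = [pid for pid in ids_a if pid not in gk]
    b_field = [pid for pid in ids_b if pid not in gk]

    def_bases = _formation_bases(len(b_field), 14.0, pitch)
    # decouple bases from the affine term so targets stay within the half
    def_bases = def_bases - (_DEF_M @ np.zeros(2))

    # initial layout
    pos = np.zeros((n_tot, 2))
    for j, pid in enumerate(a_field):
        pos[idx[pid]] = [rng.uniform(-40, 10), rng.uniform(-28, 28)]
    for j, pid in enumerate(b_field):
        pos[idx[pid]] = defender_rule(def_bases[j], np.zeros(2), pitch)
    if config.include_goalkeeper:
        pos[idx[ids_a[0]]] = [-pitch.length / 2.0 + 2.0, 0.0]
        pos[idx[ids_b[0]]] = [pitch.length / 2.0 - 2.0, 0.0]
    vel = np.zeros((n_tot, 2))
    waypoints = pos.copy()
    wp_timer = rng.uniform(0.0, 2.0, size=n_tot)

    carrier = a_field[int(rng.integers(len(a_field)))]
    ball = pos[idx[carrier]].copy()
    ball_track = np.zeros((n_frames, 2))
    pos_track = np.zeros((n_frames, n_tot, 2))

    events: list[PassEvent | ShotEvent] = []
    state = "hold"                      # hold -> lead -> flight
    t_next = rng.uniform(*config.hold_range)
    receiver: str | None = None
    flight: dict | None = None
    passes_left = int(rng.integers(*config.passes_per_possession))
    n_events = 0

    def openness(pid: str) -> float:
        p = pos[idx[pid]]
        dmin = min(
            float(np.linalg.norm(p - pos[idx[b]])) for b in b_field
        ) if b_field else 20.0
        return math.tanh(dmin / 10.0)

    margin = 0.6
    lo = np.array([-pitch.length / 2 + margin, -pitch.width / 2 + margin])
    hi = -lo

    for k in range(n_frames):
        t = k * dt
        # --- targets -------------------------------------------------------
        targets = waypoints.copy()
        speeds = np.full(n_tot, prof.max_speed * 0.75)
        # attackers: roam waypoints; carrier drifts slowly
        for pid in a_field:
            i = idx[pid]
            if wp_timer[i] <= 0 or np.linalg.norm(waypoints[i] - pos[i]) < 2.0:
                # the space-creation multiplier biases how deep (toward the
                # attacked goal, hence into valuable space) a player roams
                # capped so the deepest roamers sit just ahead of the
                # defensive block rather than behind it
                mu_x = -20.0 + 20.0 * config.skill_of(pid)
                waypoints[i] = [
                    np.clip(rng.normal(mu_x, 12.0), -45.0, 45.0),
                    rng.uniform(-29, 29),
                ]
                wp_timer[i] = rng.uniform(2.0, 5.0)
            wp_timer[i] -= dt
        if state != "flight" and carrier in idx:
            i = idx[carrier]
            targets[i] = pos[i]
            speeds[i] = 1.0
        # defenders: affine rule + noise
        for j, pid in enumerate(b_field):
            i = idx[pid]
            tgt = defender_rule(def_bases[j], ball, pitch)
            if config.defender_noise_sd > 0:
                tgt = tgt + rng.normal(0.0, config.defender_noise_sd, size=2)
            targets[i] = tgt
            speeds[i] = prof.max_speed * 0.95
        for pid in gk:
            i = idx[pid]
            gx = -pitch.length / 2 + 2.0 if pid in ids_a else pitch.length / 2 - 2.0
            targets[i] = [gx, np.clip(ball[1] * 0.3, -8, 8)]
            speeds[i] = prof.max_speed * 0.5
        targets[[idx[p] for p in a_field]] = np.clip(
            targets[[idx[p] for p in a_field]], lo + 2, hi - 2
        )

        pos, vel = _kinematic_step(
            pos, vel, targets, prof, dt, rng, config.accel_noise_sd, speeds
        )
        np.clip(pos, lo, hi, out=pos)
        disp = np.linalg.norm(vel, axis=1) * dt
        assert disp.max() <= prof.max_speed * dt + 1e-9, "speed cap violated"

        # --- ball / pass state machine ------------------------------------
        if state == "flight":
            assert flight is not None
            frac = min((t - flight["t_p"]) / flight["dur"], 1.0)
            ball = flight["origin"] + frac * (flight["dest"] - flight["origin"])
            if t + 1e-9 >= flight["t_p"] + flight["dur"]:
                if flight.get("record", True):
                    events.append(PassEvent(
                        event_id=f"e{n_events}", t_p=flight["t_p"],
                        t_r=flight["t_p"] + flight["dur"], team=flight["team"],
                        passer_id=flight["passer"], receiver_id=flight["receiver"],
                        origin=flight["origin"], destination=flight["dest"],
                        completed=True,
                    ))
                    n_events += 1
                carrier = flight["receiver"]
                end_of_possession = flight.get("final", False) and flight["team"] == "A"
                was_turnover = flight.get("turnover_leg", False)
                flight = None
                state = "hold"
                t_next = t + rng.uniform(*config.hold_range)
                if end_of_possession:
                    proxy = openness(carrier)
                    if rng.random() < config.outcome_law.p_success(proxy):
                        events.append(ShotEvent(
                            event_id=f"e{n_events}", t=t + 0.2, team="A",
                            player_id=carrier, position=pos[idx[carrier]].copy(),
                        ))
                        n_events += 1
                        # restart with a fresh attacker (unrecorded transfer)
                        new_carrier = a_field[int(rng.integers(len(a_field)))]
                        flight = {
                            "t_p": t + 0.3, "dur": 1.2, "origin": pos[idx[carrier]].copy(),
                            "dest": pos[idx[new_carrier]], "receiver": new_carrier,
                            "team": "A", "passer": carrier, "record": False,
                        }
                        state = "wait_flight"
                    else:
                        # turnover: one recorded pass by team B, then back to A
                        b_near = min(b_field, key=lambda b: np.linalg.norm(pos[idx[b]] - ball))
                        flight = {
                            "t_p": t + 0.3, "dur": 0.8, "origin": ball.copy(),
                            "dest": pos[idx[b_near]], "receiver": b_near,
                            "team": "B", "passer": carrier, "record": False,
                            "after": "b_pass",
                        }
                        state = "wait_flight"
                    passes_left = int(rng.integers(*config.passes_per_possession))
                elif was_turnover:
                    # team B completed its single pass; return ball to A
                    new_carrier = a_field[int(rng.integers(len(a_field)))]
                    flight = {
                        "t_p": t + 0.3, "dur": 1.2, "origin": pos[idx[carrier]].copy(),
                        "dest": pos[idx[new_carrier]], "receiver": new_carrier,
                        "team": "A", "passer": carrier, "record": False,
                    }
                    state = "wait_flight"
        elif state == "wait_flight":
            assert flight is not None
            if t + 1e-9 >= flight["t_p"]:
                flight["origin"] = ball.copy()
                if flight.get("after") == "b_pass":
                    flight["after"] = None
                flight["dest"] = np.array(flight["dest"], dtype=float).copy()
                d = float(np.linalg.norm(flight["dest"] - flight["origin"]))
                if flight.get("record", True):
                    flight["dur"] = config.pass_law.duration(d, rng)
                state = "flight"
        else:
            ball = pos[idx[carrier]].copy()
            if state == "hold" and t >= t_next:
                if carrier in b_field:
                    # team B plays its recorded turnover pass
                    choices = [b for b in b_field if b != carrier] or [carrier]
                    receiver = choices[int(rng.integers(len(choices)))]
                    state = "lead"
                    t_next = t + 0.3
                else:
                    choices = [p for p in a_field if p != carrier]
                    receiver = choices[int(rng.integers(len(choices)))]
                    # skill-scaled detachment toward the attacked goal,
                    # with a touch of separation from the nearest defender
                    i = idx[receiver]
                    if b_field:
                        b_near = min(b_field, key=lambda b: np.linalg.norm(pos[idx[b]] - pos[i]))
                        away = pos[i] - pos[idx[b_near]]
                        away = away / max(np.linalg.norm(away), 1e-9)
                    else:
                        away = np.array([1.0, 0.0])
                    step = np.array([1.0, 0.0]) + 0.3 * away
                    step = step / max(np.linalg.norm(step), 1e-9)
                    detach = 1.0 + 4.0 * config.skill_of(receiver)
                    waypoints[i] = np.clip(pos[i] + step * detach, lo + 2, hi - 2)
                    wp_timer[i] = config.lead_time + 2.0
                    state = "lead"
                    t_next = t + config.lead_time
            elif state == "lead" and t >= t_next:
                d = float(np.linalg.norm(pos[idx[receiver]] - pos[idx[carrier]]))
                team = "B" if carrier in b_field else "A"
                dur = config.pass_law.duration(d, rng)
                passes_left -= 1
                # passes lead the runner: aim where the receiver will be
                # at the end of the flight so they run onto the ball
                dest = np.clip(pos[idx[receiver]] + vel[idx[receiver]] * dur,
                               lo + 1, hi - 1)
                flight = {
                    "t_p": t, "dur": dur, "origin": pos[idx[carrier]].copy(),
                    "dest": dest, "receiver": receiver,
                    "team": team, "passer": carrier, "record": True,
                    "final": (passes_left <= 0) and team == "A",
                    "turnover_leg": team == "B",
                }
                # receiver runs to the meeting point
                waypoints[idx[receiver]] = dest.copy()
                state = "flight"

        np.clip(ball, lo, hi, out=ball)
        ball_track[k] = ball
        pos_track[k] = pos

    # --- assemble the tracking frame table --------------------------------
    frames = np.repeat(np.arange(n_frames), n_tot + 1)
    times = np.round(frames * dt, 6)
    agent_ids = np.tile(np.array(all_ids + [BALL_ID]), n_frames)
    teams = np.tile(np.array([pid[0] for pid in all_ids] + [BALL_ID]), n_frames)
    role_col = np.tile(np.array(roles + [BALL_ID]), n_frames)
    xy = np.concatenate([pos_track, ball_track[:, None, :]], axis=1).reshape(-1, 2)
    df = pd.DataFrame({
        "frame": frames, "t": times, "agent_id": agent_ids,
        "team": teams, "role": role_col,
        "x": np.round(xy[:, 0], 3), "y": np.round(xy[:, 1], 3),
    })
    seq = TrackingSequence(df, frame_rate=config.frame_rate)
    events.sort(key=lambda e: e.t)
    return seq, events


# ---------------------------------------------------------------------------
# triplet corpus

#: Cruise speed aimed at the center of each bin (km/h).
_BIN_TARGET_KMH = {
    "standing": 0.2,
    "walking": 4.0,
    "jogging": 10.0,
    "running": 17.0,
    "sprinting": 24.0,
}


@dataclass
class TripletCorpus:
    """Stratified single-player trajectory corpus with extracted triplets."""

    episodes: list[TrackingSequence]
    triplets: list[Triplet]
    bin_counts: dict[str, int]
    profile: KinematicProfile


def simulate_triplet_corpus(
    profile: KinematicProfile,
    n: int,
    seed: int,
    episode_length: float = 10.2,
    stride: int = 1,
    frame_rate: float = 25.0,
) -> TripletCorpus:
    """Generate at least ``n`` trajectory triplets for one player, with
    initial speeds stratified across the five velocity bins.

    Fixed-length free-space episodes are emitted round-robin over the
    bins (at least one per bin) until the extracted triplet count reaches
    ``n``; heading changes and acceleration noise give the endpoint clouds
    realistic 2-D spread while all kinematic caps hold exactly.  Bins whose
    cruise speed exceeds the player's speed cap inherit triplets only via
    noise; an empty bin at the requested n triggers a warning.
    """
    import warnings

    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    n_frames = int(round(episode_length * frame_rate)) + 1
    episodes: list[TrackingSequence] = []
    triplets: list[Triplet] = []
    bin_cycle = list(_BIN_TARGET_KMH)
    ep_i = 0
    while len(triplets) < n or ep_i < len(bin_cycle):
        bin_name = bin_cycle[ep_i % len(bin_cycle)]
        target = min(_BIN_TARGET_KMH[bin_name] / 3.6, profile.max_speed * 0.95)
        seq = _corpus_episode(profile, target, n_frames, dt, rng, frame_rate)
        episodes.append(seq)
        triplets.extend(extract_triplets(seq, "P", delta=0.2, stride=stride))
        ep_i += 1
    counts = {b: 0 for b in VELOCITY_BINS}
    for tr in triplets:
        from .movement import speed_bin
        counts[speed_bin(tr.speed)] += 1
    empty = [b for b, c in counts.items() if c == 0]
    if empty:
        warnings.warn(f"empty velocity bins at n={n}: {empty} (counts: {counts})")
    return TripletCorpus(episodes=episodes, triplets=triplets,
                         bin_counts=counts, profile=profile)


def _corpus_episode(
    profile: KinematicProfile,
    target_speed: float,
    n_frames: int,
    dt: float,
    rng: np.random.Generator,
    frame_rate: float,
) -> TrackingSequence:
    """One free-space episode cruising around a bin's nominal speed with
    gentle heading changes and realistic tempo changes — slow-downs,
    bursts and stops — so endpoint clouds fill the reachable set instead
    of collapsing onto the constant-speed arc.  No pitch bounds apply:
    the local-frame transform is translation invariant."""
    pos = np.zeros((1, 2))
    heading = rng.uniform(-math.pi, math.pi)
    vel = np.array([[math.cos(heading), math.sin(heading)]]) * target_speed
    sp = np.linalg.norm(vel)
    if sp > profile.max_speed:
        vel *= profile.max_speed / sp
    track = np.zeros((n_frames, 2))
    turn_timer = 0.0
    cruise = target_speed
    wp = pos[0] + vel[0] * 50.0 if target_speed > 0 else pos[0].copy()
    for k in range(n_frames):
        track[k] = pos[0]
        if turn_timer <= 0:
            heading += rng.normal(0.0, math.radians(25.0))
            d = np.array([math.cos(heading), math.sin(heading)])
            wp = pos[0] + d * max(target_speed, 0.5) * 20.0
            turn_timer = rng.uniform(1.0, 2.5)
        turn_timer -= dt
        # tempo: the cruise speed follows a mean-reverting random walk
        # around the bin's nominal speed, so the player brakes and bursts
        # at all phases and the endpoint cloud fills the reachable set
        sigma_s = 0.5 * target_speed + 0.1
        cruise += 0.5 * (target_speed - cruise) * dt \
            + sigma_s * math.sqrt(dt) * rng.normal()
        cruise = float(np.clip(cruise, 0.0, profile.max_speed * 0.95))
        pos, vel = _kinematic_step(
            pos, vel, wp[None, :], profile, dt, rng,
            accel_noise_sd=0.8, target_speed=np.array([cruise]),
        )
        assert np.linalg.norm(vel) <= profile.max_speed + 1e-9
    frames = np.arange(n_frames)
    df = pd.DataFrame({
        "frame": np.repeat(frames, 2),
        "t": np.round(np.repeat(frames, 2) * dt, 6),
        "agent_id": np.tile(["P", BALL_ID], n_frames),
        "team": np.tile(["A", BALL_ID], n_frames),
        "role": np.tile(["field", BALL_ID], n_frames),
        "x": np.repeat(track[:, 0], 2),
        "y": np.repeat(track[:, 1], 2),
    })
    return TrackingSequence(df, frame_rate=frame_rate)
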