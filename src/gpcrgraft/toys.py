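"""Synthetic toy 7TM receptors: the test bed for the whole pipeline.

The generator builds ideal-geometry transmembrane bundles: seven
:math:`\\alpha`-helices (1.5 Å rise, 100° twist per residue) arranged
antiparallel on a circle, smooth extracellular/intracellular loop arcs, a
short intracellular H8 helix, simplified pseudo-sidechains, and generic
residue numbers with x50 at each helix midpoint.  Conserved cysteines are
planted at 3x25 (top of TM3) and 45x50 (centre of ECL2) with geometry that
admits an exact 2.05 Å disulphide.  Controlled defects — truncations,
segment deletions, helix bulges/constrictions, engineered mutations,
distortions, dropped sidechains — are applied with truthful annotations so
that recovery tests can treat the intact twin as ground truth.

Toys are deliberately cartoonish (no Ramachandran validity, no membrane),
but every geometric contract of the pipeline is exercised faithfully.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

from .types import (
    AnnotatedSequence,
    AnnotatedStructure,
    GenericPosition,
    InputError,
    ResidueRecord,
    SequenceResidue,
    TemplateAnnotation,
    TM_SEGMENTS,
    TOPOLOGY_ORDER,
)

RISE = 1.5          # Å per residue along the helix axis
TWIST = np.deg2rad(100.0)
CA_RADIUS = 2.3     # Å, CA distance from the helix axis
NC_RADIUS = 1.9
PHASE = np.deg2rad(35.0)

# cysteine pseudo-geometry: S-C-C angle ~111 deg -> SG sits on a 69 deg cone
# about the CA->CB axis, 1.81 Å from CB
SG_BOND = 1.81
SG_AXIAL = SG_BOND * np.cos(np.deg2rad(69.0))
SG_RADIAL = SG_BOND * np.sin(np.deg2rad(69.0))
CB_BOND = 1.53
CYS_CB_GAP = 3.35   # planted CB-CB separation of the 3x25/45x50 pair

#: alphabet used for random toy sequences; cysteines only where planted
SEQ_ALPHABET = "ADEFGHIKLMNPQRSTVWY"

DEFECT_KINDS = (
    "truncate",
    "delete_segment",
    "bulge",
    "constriction",
    "mutate",
    "distort",
    "drop_sidechain",
    "diverge",
)

#: defect kinds that change the receptor itself (sequence and ground-truth
#: geometry), as opposed to crystal-artifact defects on the structure only
SELF_CONSISTENT_KINDS = ("bulge", "constriction", "diverge")


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one deterministic toy receptor."""

    helix_count: int = 7
    residues_per_helix: int = 20
    loop_lengths: tuple[tuple[str, int], ...] = (
        ("ICL1", 4), ("ECL1", 5), ("ICL2", 6), ("ECL2", 9),
        ("ICL3", 6), ("ECL3", 4),
    )
    h8_length: int = 8
    n_term: int = 2
    c_term: int = 2
    bundle_radius: float = 11.0
    seed: int = 0
    receptor: str = "TOYR1"
    structure_id: str = "TOY0001"
    gpcr_class: str = "A"
    state: str = "inactive"
    resolution: float = 2.0
    include_ligand: bool = True
    defects: tuple[tuple[str, dict[str, Any]], ...] = ()

    def loop_length(self, segment: str) -> int:
        return dict(self.loop_lengths)[segment]


@dataclass
class _Res:
    """Intermediate residue during construction (no author number yet)."""

    segment: str
    token: Optional[str]
    amino_acid: str
    atoms: dict[str, np.ndarray]
    flags: set[str] = field(default_factory=set)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InputError("zero-length direction")
    return v / n


def _perp(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to u (prefers +z)."""
    z = np.array([0.0, 0.0, 1.0])
    w = z - np.dot(z, u) * u
    if np.linalg.norm(w) < 1e-6:
        w = np.array([1.0, 0.0, 0.0]) - u[0] * u
    return _unit(w)


def _sidechain(aa: str, ca: np.ndarray, outward: np.ndarray) -> dict[str, np.ndarray]:
    """Simplified pseudo-sidechain pointing along ``outward``.

    Full heavy-atom sets for C, K, L and R (to exercise rotamer and
    disulphide code); CB plus one pseudo CG for everything else but glycine.
    """
    o = _unit(outward)
    cb = ca + CB_BOND * o
    if aa == "G":
        return {}
    if aa == "C":
        w = _perp(o)
        sg = cb + SG_AXIAL * o + SG_RADIAL * w
        return {"CB": cb, "SG": sg}
    if aa == "K":
        w = _perp(o)
        return {
            "CB": cb,
            "CG": cb + 1.5 * o + 0.3 * w,
            "CD": cb + 3.0 * o,
            "CE": cb + 4.5 * o + 0.3 * w,
            "NZ": cb + 6.0 * o,
        }
    if aa == "L":
        w = _perp(o)
        cg = cb + 1.5 * o
        return {
            "CB": cb,
            "CG": cg,
            "CD1": cg + 1.5 * _unit(o + 0.6 * w),
            "CD2": cg + 1.5 * _unit(o - 0.6 * w),
        }
    if aa == "R":
        w = _perp(o)
        cz = cb + 4.4 * o
        return {
            "CB": cb,
            "CG": cb + 1.5 * o + 0.3 * w,
            "CD": cb + 3.0 * o,
            "NE": cb + 3.7 * o + 0.3 * w,
            "CZ": cz,
            "NH1": cz + 1.3 * _unit(o + 0.8 * w),
            "NH2": cz + 1.3 * _unit(o - 0.8 * w),
        }
    return {"CB": cb, "CG": cb + 1.5 * o}


def _helix_residues(
    origin: np.ndarray,
    axis: np.ndarray,
    n1: np.ndarray,
    n2: np.ndarray,
    length: int,
    sequence: str,
) -> list[tuple[str, dict[str, np.ndarray]]]:
    """Ideal helix residues along ``axis`` (1.5 Å rise, 100° twist)."""
    out = []
    for i in range(length):
        theta = i * TWIST
        radial = np.cos(theta) * n1 + np.sin(theta) * n2
        ca = origin + RISE * i * axis + CA_RADIUS * radial
        rn = np.cos(theta - PHASE) * n1 + np.sin(theta - PHASE) * n2
        rc = np.cos(theta + PHASE) * n1 + np.sin(theta + PHASE) * n2
        n_at = origin + (RISE * i - 0.5) * axis + NC_RADIUS * rn
        c_at = origin + (RISE * i + 0.5) * axis + NC_RADIUS * rc
        o_at = c_at + 1.23 * rc
        aa = sequence[i]
        atoms = {"N": n_at, "CA": ca, "C": c_at, "O": o_at}
        atoms.update(_sidechain(aa, ca, radial))
        out.append((aa, atoms))
    return out


def _bezier(p0: np.ndarray, ctrl: np.ndarray, p1: np.ndarray, t: float) -> np.ndarray:
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * ctrl + t**2 * p1


def _bezier_tangent(p0, ctrl, p1, t):
    return _unit(2 * (1 - t) * (ctrl - p0) + 2 * t * (p1 - ctrl))


def _loop_backbone(ca: np.ndarray, tangent: np.ndarray, zsign: float, aa: str) -> dict:
    # N and C sit off the tangent line so the N/CA/C frame is never collinear
    drop = _perp(tangent)
    n_at = ca - 0.6 * tangent - 0.35 * drop
    c_at = ca + 0.6 * tangent - 0.35 * drop
    o_at = c_at + np.array([0.0, 0.0, zsign])
    atoms = {"N": n_at, "CA": ca, "C": c_at, "O": o_at}
    out = ca[:2]
    outward = np.array([out[0], out[1], 0.0])
    if np.linalg.norm(outward) < 1e-6:
        outward = np.array([1.0, 0.0, 0.0])
    atoms.update(_sidechain(aa, ca, _unit(outward) + np.array([0, 0, 0.4 * zsign])))
    return atoms


def _loop_tokens(segment: str, n: int) -> tuple[list[str], int]:
    """Loop tokens centred on x50; returns tokens and the centre index."""
    from .types import SEGMENT_CODES

    code = SEGMENT_CODES[segment]
    centre = n // 2
    return [f"{code}x{50 - centre + j}" for j in range(n)], centre


def _helix_tokens(code: str, length: int) -> list[str]:
    mid = length // 2
    return [f"{code}x{50 - mid + i}" for i in range(length)]


class _Builder:
    def __init__(self, spec: ToySpec):
        if spec.helix_count != 7:
            raise InputError("toy bundles are 7TM; helix_count must be 7")
        if spec.residues_per_helix < 10:
            raise InputError("residues_per_helix must be >= 10")
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.residues: list[_Res] = []
        self.mutations: list[dict] = []
        self.missing_segments: list[str] = []
        self.distorted: list[dict] = []

    # -- intact construction -------------------------------------------------

    def build_intact(self) -> None:
        spec = self.spec
        L = spec.residues_per_helix
        half = RISE * (L - 1) / 2.0
        R = spec.bundle_radius
        z = np.array([0.0, 0.0, 1.0])

        helix_info = {}
        for k in range(7):
            phi = 2 * np.pi * k / 7
            axis_xy = np.array([R * np.cos(phi), R * np.sin(phi), 0.0])
            down = k % 2 == 0  # TM1, TM3, TM5, TM7 run extracellular -> in
            axis = -z if down else z
            origin = axis_xy + np.array([0.0, 0.0, half if down else -half])
            n1 = np.array([np.cos(phi), np.sin(phi), 0.0])
            n2 = np.array([-np.sin(phi), np.cos(phi), 0.0])
            helix_info[f"TM{k + 1}"] = (origin, axis, n1, n2)

        # draw the full sequence first so that every variant of the same
        # seed shares it
        seg_plan: list[tuple[str, int]] = [("N-term", spec.n_term)]
        for k in range(7):
            seg_plan.append((f"TM{k + 1}", L))
            if k < 6:
                loop = TOPOLOGY_ORDER[TOPOLOGY_ORDER.index(f"TM{k + 1}") + 1]
                seg_plan.append((loop, spec.loop_length(loop)))
        seg_plan.append(("H8", spec.h8_length))
        seg_plan.append(("C-term", spec.c_term))

        seqs = {}
        for seg, n in seg_plan:
            seqs[seg] = "".join(self.rng.choice(list(SEQ_ALPHABET), size=n))

        # plant the conserved cysteines
        tm3_tokens = _helix_tokens("3", L)
        tm3_tokens[0] = "3x25"  # schematic label for the disulphide-bearing top
        seqs["TM3"] = "C" + seqs["TM3"][1:]
        ecl2_tokens, cys_idx = _loop_tokens("ECL2", spec.loop_length("ECL2"))
        s = list(seqs["ECL2"])
        s[cys_idx] = "C"
        seqs["ECL2"] = "".join(s)

        # N-term tail (above the extracellular rim, toward TM1)
        tm1_origin = helix_info["TM1"][0]
        for j in range(spec.n_term):
            ca = tm1_origin + np.array([0.0, 0.0, 3.8 * (spec.n_term - j)])
            atoms = {
                "N": ca + np.array([-1.2, 0.35, 0.3]),
                "CA": ca,
                "C": ca + np.array([1.2, 0.35, -0.3]),
                "O": ca + np.array([1.6, 1.0, -0.3]),
            }
            aa = seqs["N-term"][j]
            atoms.update(_sidechain(aa, ca, np.array([0.0, 1.0, 0.0])))
            self.residues.append(_Res("N-term", None, aa, atoms))

        helix_resids: dict[str, list[tuple[str, dict]]] = {}
        for seg, (origin, axis, n1, n2) in helix_info.items():
            helix_resids[seg] = _helix_residues(origin, axis, n1, n2, L, seqs[seg])

        # H8: horizontal helix after TM7, below the intracellular face
        phi7 = 2 * np.pi * 6 / 7
        t_hat = np.array([-np.sin(phi7), np.cos(phi7), 0.0])
        h8_origin = helix_info["TM7"][0] + np.array([0.0, 0.0, -2 * half - 3.0])
        h8_n1 = np.array([np.cos(phi7), np.sin(phi7), 0.0])
        h8_n2 = np.array([0.0, 0.0, -1.0])
        h8 = _helix_residues(h8_origin, t_hat, h8_n1, h8_n2, spec.h8_length, seqs["H8"])

        token_map = {f"TM{k + 1}": _helix_tokens(str(k + 1), L) for k in range(7)}
        token_map["TM3"] = tm3_tokens
        token_map["H8"] = _helix_tokens("8", spec.h8_length)

        # interleave helices and loops in topology order
        for k in range(7):
            seg = f"TM{k + 1}"
            for tok, (aa, atoms) in zip(token_map[seg], helix_resids[seg]):
                self.residues.append(_Res(seg, tok, aa, atoms))
            if k < 6:
                loop = TOPOLOGY_ORDER[TOPOLOGY_ORDER.index(seg) + 1]
                self._build_loop(loop, helix_resids, helix_info, seqs[loop])
        for tok, (aa, atoms) in zip(token_map["H8"], h8):
            self.residues.append(_Res("H8", tok, aa, atoms))

        last_h8_ca = h8[-1][1]["CA"]
        for j in range(spec.c_term):
            ca = last_h8_ca + (j + 1) * 3.8 * t_hat
            atoms = {
                "N": ca + np.array([-1.2, 0.35, 0.3]),
                "CA": ca,
                "C": ca + np.array([1.2, 0.35, -0.3]),
                "O": ca + np.array([1.6, 1.0, -0.3]),
            }
            aa = seqs["C-term"][j]
            atoms.update(_sidechain(aa, ca, np.array([0.0, 0.0, -1.0])))
            self.residues.append(_Res("C-term", None, aa, atoms))

    def _build_loop(self, loop: str, helix_resids, helix_info, seq: str) -> None:
        spec = self.spec
        n = spec.loop_length(loop)
        prev_tm = TOPOLOGY_ORDER[TOPOLOGY_ORDER.index(loop) - 1]
        next_tm = TOPOLOGY_ORDER[TOPOLOGY_ORDER.index(loop) + 1]
        p = helix_resids[prev_tm][-1][1]["CA"]
        q = helix_resids[next_tm][0][1]["CA"]
        zsign = 1.0 if loop.startswith("E") else -1.0
        tokens, centre = _loop_tokens(loop, n)

        if loop == "ECL2":
            # route through the planted 45x50 cysteine atop TM3
            tm3_first = helix_resids["TM3"][0][1]
            ca1 = tm3_first["CA"]
            cb1 = tm3_first["CB"]
            u = _unit(cb1 - ca1)
            x = ca1 + (CB_BOND + CYS_CB_GAP + CB_BOND) * u  # CA of 45x50
            self._append_loop_arc(loop, p, x, seq[:centre], tokens[:centre], zsign)
            t_hat = _unit(q - p)
            drop = _perp(t_hat)
            atoms = {
                "N": x - 0.7 * t_hat - 0.35 * drop,
                "CA": x,
                "C": x + 0.7 * t_hat - 0.35 * drop,
                "O": x + 0.7 * t_hat + np.array([0.0, 0.0, 1.0]),
            }
            cb2 = x - CB_BOND * u
            w = _perp(u)
            atoms["CB"] = cb2
            atoms["SG"] = cb2 - SG_AXIAL * u + SG_RADIAL * w
            self.residues.append(_Res(loop, tokens[centre], "C", atoms))
            self._append_loop_arc(
                loop, x, q, seq[centre + 1 :], tokens[centre + 1 :], zsign
            )
        else:
            self._append_loop_arc(loop, p, q, seq, tokens, zsign)

    def _append_loop_arc(self, loop, p, q, seq, tokens, zsign) -> None:
        n = len(seq)
        if n == 0:
            return
        mid = (p + q) / 2.0
        out_xy = mid[:2]
        radial = (
            np.array([out_xy[0], out_xy[1], 0.0]) / max(np.linalg.norm(out_xy), 1e-6)
        )
        ctrl = mid + 2.5 * radial + np.array([0.0, 0.0, zsign * (2.0 + 0.5 * n)])
        for j in range(n):
            t = (j + 1) / (n + 1)
            ca = _bezier(p, ctrl, q, t)
            tan = _bezier_tangent(p, ctrl, q, t)
            atoms = _loop_backbone(ca, tan, zsign, seq[j])
            self.residues.append(_Res(loop, tokens[j], seq[j], atoms))

    # -- defects -------------------------------------------------------------

    def _index_of_token(self, token: str) -> int:
        for i, r in enumerate(self.residues):
            if r.token == token:
                return i
        raise InputError(f"defect target {token} not present in the toy")

    def _segment_indices(self, segment: str) -> list[int]:
        idx = [i for i, r in enumerate(self.residues) if r.segment == segment]
        if not idx:
            raise InputError(f"defect segment {segment} not present in the toy")
        return idx

    def _rearc_window(self, lo: int, hi: int, bulge_out: float) -> None:
        """Re-lay CAs of residues (lo, hi) exclusive on an outward arc."""
        a = self.residues[lo].atoms["CA"]
        b = self.residues[hi].atoms["CA"]
        interior = self.residues[lo + 1 : hi]
        n = len(interior)
        mid = (a + b) / 2.0
        out_xy = np.array([mid[0], mid[1], 0.0])
        radial = out_xy / max(np.linalg.norm(out_xy), 1e-6)
        ctrl = mid + bulge_out * radial
        for j, res in enumerate(interior):
            t = (j + 1) / (n + 1)
            ca = _bezier(a, ctrl, b, t)
            tan = _bezier_tangent(a, ctrl, b, t)
            drop = _perp(tan)
            n_at = ca - 0.6 * tan - 0.35 * drop
            c_at = ca + 0.6 * tan - 0.35 * drop
            atoms = {"N": n_at, "CA": ca, "C": c_at, "O": c_at + 1.0 * radial}
            atoms.update(_sidechain(res.amino_acid, ca, radial))
            res.atoms = atoms

    def apply_defect(self, kind: str, params: dict) -> None:
        if kind not in DEFECT_KINDS:
            raise InputError(f"unknown defect kind {kind!r}")
        getattr(self, f"_defect_{kind}")(**params)

    def _defect_bulge(self, segment: str, after: str) -> None:
        if segment not in TM_SEGMENTS:
            raise InputError(f"bulge outside a TM helix ({segment}) is impossible")
        ia = self._index_of_token(after)
        seg_idx = self._segment_indices(segment)
        if ia - 2 < seg_idx[0] or ia + 3 > seg_idx[-1]:
            raise InputError(f"bulge window around {after} leaves helix {segment}")
        aa = str(self.rng.choice(list(SEQ_ALPHABET)))
        new = _Res(segment, after + "1", aa, dict(self.residues[ia].atoms))
        self.residues.insert(ia + 1, new)
        self._rearc_window(ia - 2, ia + 4, 4.5)

    def _defect_constriction(self, segment: str, at: str) -> None:
        if segment not in TM_SEGMENTS:
            raise InputError(f"constriction outside a TM helix is impossible")
        ia = self._index_of_token(at)
        seg_idx = self._segment_indices(segment)
        if ia - 3 < seg_idx[0] or ia + 3 > seg_idx[-1]:
            raise InputError(f"constriction window around {at} leaves helix {segment}")
        del self.residues[ia]
        self._rearc_window(ia - 3, ia + 2, 1.5)

    def _defect_diverge(self, n: int) -> None:
        """Re-type n random positions: a genuinely different receptor."""
        eligible = [
            i
            for i, r in enumerate(self.residues)
            if r.token not in ("3x25", "45x50") and r.amino_acid != "G"
        ]
        pick = self.rng.choice(eligible, size=min(n, len(eligible)), replace=False)
        for i in sorted(pick):
            r = self.residues[i]
            old = r.amino_acid
            choices = [a for a in SEQ_ALPHABET if a != old]
            r.amino_acid = str(self.rng.choice(choices))
            self._retype_sidechain(r)

    def _retype_sidechain(self, r: _Res) -> None:
        ca = r.atoms["CA"]
        if "CB" in r.atoms:
            outward = r.atoms["CB"] - ca
        else:
            outward = np.array([ca[0], ca[1], 0.0])
            if np.linalg.norm(outward) < 1e-6:
                outward = np.array([1.0, 0.0, 0.0])
        backbone = {k: v for k, v in r.atoms.items() if k in ("N", "CA", "C", "O")}
        backbone.update(_sidechain(r.amino_acid, ca, _unit(outward)))
        r.atoms = backbone

    def _defect_truncate(self, segment: str, n: int, end: str = "C") -> None:
        idx = self._segment_indices(segment)
        if n >= len(idx):
            raise InputError(f"truncation of {n} would empty segment {segment}")
        victims = idx[:n] if end == "N" else idx[-n:]
        for i in sorted(victims, reverse=True):
            del self.residues[i]

    def _defect_delete_segment(self, segment: str, keep: Sequence[str] = ()) -> None:
        idx = self._segment_indices(segment)
        for i in sorted(idx, reverse=True):
            if self.residues[i].token not in keep:
                del self.residues[i]
        if not keep:
            self.missing_segments.append(segment)

    def _defect_distort(
        self, segment: str, first: str, last: str, magnitude: float = 3.0
    ) -> None:
        lo = GenericPosition.from_token(first).ordinal
        hi = GenericPosition.from_token(last).ordinal
        hit = 0
        for r in self.residues:
            if r.segment != segment or r.token is None:
                continue
            o = GenericPosition.from_token(r.token).ordinal
            if lo <= o <= hi:
                ca = r.atoms["CA"]
                radial = np.array([ca[0], ca[1], 0.0])
                radial = radial / max(np.linalg.norm(radial), 1e-6)
                shift = magnitude * radial + self.rng.normal(0.0, 0.3, size=3)
                r.atoms = {k: v + shift for k, v in r.atoms.items()}
                r.flags.add("distorted")
                hit += 1
        if hit == 0:
            raise InputError(f"distortion range {first}-{last} hits no residue")
        self.distorted.append({"segment": segment, "first": first, "last": last})

    def _defect_mutate(
        self, token: str, new_aa: str, engineered: bool = True
    ) -> None:
        i = self._index_of_token(token)
        r = self.residues[i]
        old = r.amino_acid
        if new_aa == old:
            # deterministic fallback so canned defect lists work for any seed
            alphabet = SEQ_ALPHABET
            new_aa = alphabet[(alphabet.find(old) + 1) % len(alphabet)]
        r.amino_acid = new_aa
        self._retype_sidechain(r)
        if engineered:
            r.flags.add("engineered_mutation")
            self.mutations.append(
                {"generic": token, "construct_aa": new_aa, "wildtype_aa": old}
            )

    def _defect_drop_sidechain(self, token: str) -> None:
        i = self._index_of_token(token)
        r = self.residues[i]
        r.atoms = {k: v for k, v in r.atoms.items() if k in ("N", "CA", "C", "O")}


def generate_toy_receptor(
    spec: ToySpec,
) -> tuple[AnnotatedStructure, AnnotatedSequence, TemplateAnnotation]:
    """Build one toy receptor: structure, sequence and truthful annotation.

    Self-consistent defects (bulge, constriction, diverge) alter the
    receptor itself — sequence and ground-truth structure agree.  The
    remaining kinds emulate crystal artifacts: they alter the structure
    only, and the annotation records them truthfully.
    """
    b = _Builder(spec)
    b.build_intact()

    def is_self_consistent(d) -> bool:
        kind, params = d
        if kind == "mutate":
            return not params.get("engineered", True)
        return kind in SELF_CONSISTENT_KINDS

    ordered = sorted(spec.defects, key=lambda d: 0 if is_self_consistent(d) else 1)
    # sequence snapshot is taken after self-consistent defects only
    n_self = sum(1 for d in ordered if is_self_consistent(d))
    for kind, params in ordered[:n_self]:
        b.apply_defect(kind, dict(params))

    seq_residues = [
        SequenceResidue(
            index=i + 1,
            amino_acid=r.amino_acid,
            segment=r.segment,
            generic=None if r.token is None else GenericPosition.from_token(r.token),
        )
        for i, r in enumerate(b.residues)
    ]
    sequence = AnnotatedSequence(
        receptor=spec.receptor, gpcr_class=spec.gpcr_class, residues=seq_residues
    )
    sequence.validate()

    for kind, params in ordered[n_self:]:
        b.apply_defect(kind, dict(params))

    residues = []
    borders: dict[str, tuple[int, int]] = {}
    for i, r in enumerate(b.residues):
        num = i + 1
        residues.append(
            ResidueRecord(
                chain="A",
                author_number=num,
                amino_acid=r.amino_acid,
                generic=None if r.token is None else GenericPosition.from_token(r.token),
                atoms=dict(r.atoms),
                flags=set(r.flags),
            )
        )
        lo, hi = borders.get(r.segment, (num, num))
        borders[r.segment] = (min(lo, num), max(hi, num))

    ligand = None
    if spec.include_ligand:
        half = RISE * (spec.residues_per_helix - 1) / 2.0
        phi3 = 2 * np.pi * 2 / 7
        centre = np.array([6.5 * np.cos(phi3), 6.5 * np.sin(phi3), half - 4.0])
        ligand = [
            centre,
            centre + np.array([1.4, 0.0, 0.0]),
            centre + np.array([0.0, 1.4, -1.0]),
        ]

    structure = AnnotatedStructure(
        id=spec.structure_id,
        receptor=spec.receptor,
        residues=residues,
        segment_borders=borders,
        ligand_atoms=ligand,
    )
    structure.validate()

    annotation = TemplateAnnotation(
        structure_id=spec.structure_id,
        receptor=spec.receptor,
        gpcr_class=spec.gpcr_class,
        state=spec.state,
        resolution=spec.resolution,
        preferred_chain="A",
        missing_segments=list(b.missing_segments),
        distorted_ranges=b.distorted,
        mutations=b.mutations,
    )
    return structure, sequence, annotation


def make_template_catalog(
    base: ToySpec,
    variants: Sequence[Any],
) -> list[tuple[AnnotatedStructure, TemplateAnnotation]]:
    """Intact twin plus one defect-bearing structure per variant.

    Each variant is either a plain list of ``(kind, params)`` defects or a
    dict with optional keys ``id``, ``receptor``, ``resolution``, ``state``,
    ``seed`` and ``defects``.  Every entry's annotation is truthful, so
    recovery tests may treat the intact twin as ground truth.
    """
    catalog: list[tuple[AnnotatedStructure, TemplateAnnotation]] = []
    intact, _, intact_ann = generate_toy_receptor(base)
    catalog.append((intact, intact_ann))
    for i, var in enumerate(variants):
        if isinstance(var, dict):
            defects = tuple((k, dict(p)) for k, p in var.get("defects", ()))
            overrides = {
                key: var[key]
                for key in ("receptor", "resolution", "state", "seed")
                if key in var
            }
            sid = var.get("id", f"{base.structure_id}_V{i + 1:02d}")
        else:
            defects = tuple((k, dict(p)) for k, p in var)
            overrides = {}
            sid = f"{base.structure_id}_V{i + 1:02d}"
        vspec = dataclasses.replace(
            base,
            structure_id=sid,
            defects=base.defects + defects,
            **overrides,
        )
        structure, _, annotation = generate_toy_receptor(vspec)
        catalog.append((structure, annotation))
    ids = [ann.structure_id for _, ann in catalog]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate structure ids in catalog: {ids}")
    return catalog


# --- synthetic bioactivity data ---------------------------------------------

_VIOLATION_KINDS = ("no_pchembl", "validity_comment", "activity_comment", "assay_other")


def generate_activity_records(
    n: int,
    n_ligands: int = 40,
    n_targets: int = 8,
    violation_rate: float = 0.0,
    seed: int = 0,
):
    """Synthetic assay records emulating a curated bioactivity extraction.

    pChEMBL values are uniform in [4, 10]; a ``violation_rate`` fraction of
    records gets a planted validity violation (missing pChEMBL,
    disqualifying comment, or non-binding/functional assay type).  The
    manifest records the exact planted counts; output is deterministic per
    seed.  Returns ``(records, manifest)``.
    """
    from .ligands import ActivityRecord

    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    species_pool = ("Homo sapiens", "Rattus norvegicus", "Mus musculus")
    records = []
    for i in range(n):
        records.append(
            dict(
                ligand_id=f"LIG{int(rng.integers(1, n_ligands + 1)):05d}",
                target_id=f"RCPT{int(rng.integers(1, n_targets + 1)):03d}",
                species=str(rng.choice(species_pool)),
                assay_type=str(rng.choice(["binding", "functional"])),
                pchembl=float(np.round(rng.uniform(4.0, 10.0), 2)),
                validity_comment=None,
                activity_comment=None,
                source_ref=f"ASSAY{i + 1:06d}",
            )
        )

    k = int(round(n * violation_rate))
    planted: dict[str, list[int]] = {kind: [] for kind in _VIOLATION_KINDS}
    if k > 0:
        victims = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
        for j, idx in enumerate(victims):
            kind = _VIOLATION_KINDS[j % len(_VIOLATION_KINDS)]
            planted[kind].append(idx)
            if kind == "no_pchembl":
                records[idx]["pchembl"] = None
            elif kind == "validity_comment":
                records[idx]["validity_comment"] = "Potential transcription error"
            elif kind == "activity_comment":
                records[idx]["activity_comment"] = "inconclusive"
            else:
                records[idx]["assay_type"] = "other"

    manifest = {
        "n": n,
        "seed": seed,
        "violation_rate": violation_rate,
        "planted_total": k,
        "planted_by_kind": {kind: len(v) for kind, v in planted.items()},
        "planted_indices": {kind: v for kind, v in planted.items()},
    }
    return [ActivityRecord(**r) for r in records], manifest


def generate_ligand_set(n: int, seed: int = 0, vendor_fraction: float = 0.7):
    """Synthetic ligand property records for property/vendor filter tests."""
    from .ligands import LigandProperties

    rng = np.random.default_rng(seed)
    out = []
    for i in range(1, n + 1):
        has_vendor = rng.random() < vendor_fraction
        has_logp = rng.random() < 0.9
        out.append(
            LigandProperties(
                ligand_id=f"LIG{i:05d}",
                smiles="C" * int(rng.integers(1, 20)),
                molecular_weight=float(np.round(rng.uniform(150.0, 700.0), 1)),
                hbd=int(rng.integers(0, 6)),
                hba=int(rng.integers(0, 11)),
                rotatable_bonds=int(rng.integers(0, 13)),
                logp=float(np.round(rng.normal(2.0, 1.5), 2)) if has_logp else None,
                vendors=(("ToyChem", f"TC-{i:05d}"),) if has_vendor else (),
            )
        )
    return out
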