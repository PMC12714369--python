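"""Feed-forward loop enumeration and coherent/incoherent classification.

A feed-forward loop (FFL) is an ordered triple (tf1, tf2, target): tf1
binds the promoter of tf2, and both tf1 and tf2 bind the promoter of a
common target, with all three nodes distinct. With edge polarities
s1 = sign(tf1->tf2), s2 = sign(tf2->target), s3 = sign(tf1->target),
the loop is coherent when the indirect-path sign equals the direct-edge
sign (s1*s2 == s3) and incoherent otherwise. The eight sign patterns
map onto the canonical coherent types c1-c4 and incoherent types i1-i4
(Mangan-Alon taxonomy); the mapping is pinned in SIGN_TYPE_TABLE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import DomainError
from .gini import (
    POLARITY_ACTIVATING,
    POLARITY_REPRESSING,
    SignedNetwork,
)
from .network import RegulatoryNetwork

SIGN_PLUS = "+"
SIGN_MINUS = "-"
SIGN_UNDETERMINED = "undetermined"
UNCLASSIFIED = "unclassified"

#: authoritative (s1, s2, s3) -> type table; s1 = tf1->tf2, s2 = tf2->target,
#: s3 = tf1->target. Coherent iff s1*s2 == s3.
SIGN_TYPE_TABLE: dict[tuple[str, str, str], str] = {
    ("+", "+", "+"): "c1",
    ("-", "+", "-"): "c2",
    ("+", "-", "-"): "c3",
    ("-", "-", "+"): "c4",
    ("+", "-", "+"): "i1",
    ("-", "-", "-"): "i2",
    ("+", "+", "-"): "i3",
    ("-", "+", "+"): "i4",
}

COHERENT_TYPES = frozenset({"c1", "c2", "c3", "c4"})
INCOHERENT_TYPES = frozenset({"i1", "i2", "i3", "i4"})


@dataclass
class FFLInstance:
    tf1: str
    tf2: str
    target: str
    signs: tuple[str, str, str] = (
        SIGN_UNDETERMINED,
        SIGN_UNDETERMINED,
        SIGN_UNDETERMINED,
    )
    ffl_type: str = UNCLASSIFIED
    context: str = ""
    gccs: tuple[float, float, float] = field(
        default=(float("nan"),) * 3
    )

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.tf1, self.tf2, self.target)


def classify_ffl(signs: tuple[str, str, str]) -> str:
    """Map a sign triple (s1, s2, s3) to c1-c4 / i1-i4 / unclassified."""
    for s in signs:
        if s not in (SIGN_PLUS, SIGN_MINUS, SIGN_UNDETERMINED):
            raise DomainError(f"invalid sign token {s!r}")
    if SIGN_UNDETERMINED in signs:
        return UNCLASSIFIED
    return SIGN_TYPE_TABLE[tuple(signs)]  # type: ignore[index]


def enumerate_ffls(
    net: RegulatoryNetwork, ordered: bool = True
) -> list[FFLInstance]:
    """All FFL instances of a network (signs undetermined).

    With ``ordered=True`` (default) the pair (tf1, tf2) is directional:
    (A, B, p) and (B, A, p) are distinct instances when both TF->TF
    edges exist. ``ordered=False`` collapses such mirror pairs, keeping
    the lexicographically smaller TF first.
    """
    out = net.out_neighbors()
    found: list[FFLInstance] = []
    for tf1 in sorted(out):
        for tf2 in sorted(out[tf1]):
            if tf2 == tf1 or tf2 not in out:
                continue
            common = (out[tf1] & out[tf2]) - {tf1, tf2}
            for target in sorted(common):
                found.append(FFLInstance(tf1, tf2, target))
    if not ordered:
        seen: dict[tuple[str, str, str], FFLInstance] = {}
        for inst in found:
            a, b = sorted((inst.tf1, inst.tf2))
            key = (a, b, inst.target)
            if key not in seen:
                seen[key] = inst
        found = list(seen.values())
    return found


def attach_signs(
    inst: FFLInstance, polarity_of: dict[tuple[str, str], object], context: str
) -> FFLInstance:
    """Return a copy of ``inst`` with per-context signs and type filled in."""

    def tok(tf: str, prom: str) -> tuple[str, float]:
        edge = polarity_of.get((tf, prom))
        if edge is None:
            return SIGN_UNDETERMINED, float("nan")
        pol = edge.polarity  # type: ignore[attr-defined]
        gcc = edge.gcc  # type: ignore[attr-defined]
        if pol == POLARITY_ACTIVATING:
            return SIGN_PLUS, gcc
        if pol == POLARITY_REPRESSING:
            return SIGN_MINUS, gcc
        return SIGN_UNDETERMINED, gcc

    s1, g1 = tok(inst.tf1, inst.tf2)
    s2, g2 = tok(inst.tf2, inst.target)
    s3, g3 = tok(inst.tf1, inst.target)
    signs = (s1, s2, s3)
    return FFLInstance(
        inst.tf1,
        inst.tf2,
        inst.target,
        signs=signs,
        ffl_type=classify_ffl(signs),
        context=context,
        gccs=(g1, g2, g3),
    )


@dataclass
class SignificantFFLs:
    context: str
    significant: list[FFLInstance]
    unclassified: list[FFLInstance]
    type_counts: dict[str, int]


def significant_ffls(
    snet: SignedNetwork, ffls: list[FFLInstance], context: str
) -> SignificantFFLs:
    """Classify FFLs using a signed network's per-context polarities.

    Only instances whose all three edges have determined polarity
    (|GCC| beyond the signing threshold) are retained as significant;
    the rest are reported as unclassified.
    """
    lookup = snet.polarity_lookup(context)
    significant: list[FFLInstance] = []
    unclassified: list[FFLInstance] = []
    counts: dict[str, int] = {}
    for inst in ffls:
        signed = attach_signs(inst, lookup, context)
        if signed.ffl_type == UNCLASSIFIED:
            unclassified.append(signed)
        else:
            significant.append(signed)
            counts[signed.ffl_type] = counts.get(signed.ffl_type, 0) + 1
    return SignificantFFLs(context, significant, unclassified, counts)


def ffls_to_frame(ffls: list[FFLInstance]) -> pd.DataFrame:
    rows = [
        {
            "tf1": f.tf1,
            "tf2": f.tf2,
            "target": f.target,
            "context": f.context,
            "s1": f.signs[0],
            "s2": f.signs[1],
            "s3": f.signs[2],
            "gcc1": f.gccs[0],
            "gcc2": f.gccs[1],
            "gcc3": f.gccs[2],
            "ffl_type": f.ffl_type,
        }
        for f in ffls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "tf1", "tf2", "target", "context",
            "s1", "s2", "s3", "gcc1", "gcc2", "gcc3", "ffl_type",
        ],
    )
    return df.sort_values(["tf1", "tf2", "target"]).reset_index(drop=True)
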