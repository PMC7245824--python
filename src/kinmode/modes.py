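"""Kinase inhibitor binding-mode labels.

Binding modes are crystallographically defined classes of kinase-inhibitor
complexes: type I inhibitors bind the active (DFG-in / alphaC-in) kinase
conformation, type II the inactive DFG-out conformation with an adjacent
hydrophobic back pocket, and type I1/2 the intermediate DFG-in / alphaC-out
state. Only these three classes are modelled here; allosteric, covalent and
bivalent inhibitors (types III-VI) are out of scope.
"""

from __future__ import annotations

import enum


class BindingMode(str, enum.Enum):
    """The three admissible kinase inhibitor binding modes."""

    TYPE_I = "I"
    TYPE_I_HALF = "I1/2"
    TYPE_II = "II"

    def __str__(self) -> str:  # serialized form is the short label
        return self.value


#: Canonical class order used everywhere (probability columns, tie-breaks).
MODE_ORDER: tuple[BindingMode, ...] = (
    BindingMode.TYPE_I,
    BindingMode.TYPE_I_HALF,
    BindingMode.TYPE_II,
)

#: Fixed plotting colors: type I blue, I1/2 orange, II green.
MODE_COLORS: dict[BindingMode, str] = {
    BindingMode.TYPE_I: "tab:blue",
    BindingMode.TYPE_I_HALF: "tab:orange",
    BindingMode.TYPE_II: "tab:green",
}


def mode_from_label(label: str) -> BindingMode:
    """Parse a serialized binding-mode label ("I", "I1/2", "II")."""
    try:
        return BindingMode(label)
    except ValueError:
        raise ValueError(
            f"unknown binding mode label {label!r}; expected one of "
            f"{[m.value for m in MODE_ORDER]}"
        ) from None


def labels_to_codes(labels) -> "list[int]":
    """Map BindingMode labels to integer codes 0/1/2 in canonical order."""
    index = {m: i for i, m in enumerate(MODE_ORDER)}
    return [index[m] for m in labels]
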