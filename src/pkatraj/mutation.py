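"""Alanine pseudo-mutation: in-place side-chain truncation.

A pseudo-mutation replaces a residue's side chain with alanine's while keeping
every other coordinate in the protein unchanged.  It is a coordinate-preserving
probe for attributing pKa shifts to specific neighbours — not an estimate of
the pKa in a real mutant, which would require re-sampling the mutant ensemble.

Truncation keeps the backbone (N, CA, C, O, plus OXT on a C-terminus and any
backbone/CB hydrogens) and CB, renames the residue ALA, and deletes everything
beyond CB.  No CB reconstruction and no minimization are performed.  Glycine
cannot be mutated (it lacks the CB alanine requires).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .trajectory import Atom, FrameSnapshot, ResidueKey

__all__ = ["MutationSpec", "MutationError", "apply_alanine_mutation"]


class MutationError(ValueError):
    """Invalid pseudo-mutation request (missing target, GLY target, ...)."""


#: Heavy atoms retained in a truncated (alanine) residue.  OXT is kept when
#: present: it is a backbone atom of the C-terminal carboxylate.
ALANINE_HEAVY_ATOMS = frozenset({"N", "CA", "C", "O", "CB", "OXT"})

#: Hydrogens retained: backbone amide/terminal H, HA, and H on the kept CB.
_KEPT_HYDROGENS = frozenset({"H", "H1", "H2", "H3", "HN", "HA", "HA2", "HA3"})


@dataclass(frozen=True)
class MutationSpec:
    """Residues to pseudo-mutate to alanine, addressed by (chain_id, resid)."""

    targets: tuple[tuple[str, int], ...]

    @classmethod
    def from_strings(cls, specs: Iterable[str]) -> "MutationSpec":
        """Parse ``CHAIN:RESID`` items, e.g. ``["A:44", "A:114"]``."""
        targets = []
        for item in specs:
            for part in str(item).split(","):
                part = part.strip()
                if not part:
                    continue
                try:
                    chain, resid = part.split(":")
                    targets.append((chain.strip(), int(resid)))
                except ValueError as exc:
                    raise MutationError(
                        f"malformed mutation spec {part!r}; expected CHAIN:RESID"
                    ) from exc
        return cls(tuple(targets))

    def matches(self, key: ResidueKey) -> bool:
        return (key.chain_id, key.resid) in set(self.targets)


def _keep_atom(atom: Atom) -> bool:
    name = atom.name
    if name in ALANINE_HEAVY_ATOMS:
        return True
    if atom.is_hydrogen:
        return name in _KEPT_HYDROGENS or name.startswith("HB")
    return False


def apply_alanine_mutation(
    snapshot: FrameSnapshot, spec: MutationSpec
) -> FrameSnapshot:
    """Truncate each target residue to the alanine atom set, coordinates kept.

    Every non-target atom is returned bit-identical to the input, in the same
    order.  Raises :class:`MutationError` when a target is absent from the
    structure or is a glycine.
    """
    present = {(k.chain_id, k.resid): k for k in snapshot.residues()}
    for chain, resid in spec.targets:
        key = present.get((chain, resid))
        if key is None:
            raise MutationError(f"mutation target {chain}:{resid} not in structure")
        if key.resname == "GLY":
            raise MutationError(
                f"cannot pseudo-mutate GLY {chain}:{resid}: glycine has no CB"
            )

    target_set = set(spec.targets)
    renamed: dict[ResidueKey, ResidueKey] = {}
    new_atoms = []
    for atom in snapshot.atoms:
        key = atom.residue
        if (key.chain_id, key.resid) not in target_set:
            new_atoms.append(atom)
            continue
        if not _keep_atom(atom):
            continue
        if key not in renamed:
            renamed[key] = replace(key, resname="ALA")
        new_atoms.append(replace(atom, residue=renamed[key]))
    return FrameSnapshot(snapshot.frame_index, snapshot.time_ps, new_atoms)
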