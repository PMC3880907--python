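"""Deterministic 128-bit asset identifiers.

Every asset managed by the system carries a deterministic UUID (dUUID) used as
a tracking number: it is not drawn at random but computed from what the asset
*is* (its content checksums) or from the process that produced it (activity
name, version, parameters and input identifiers).  Identical content therefore
always maps to the identical identifier, on any platform — which is what turns
accidental re-archival, re-extraction or re-processing into an immediate,
detectable identifier collision instead of silent duplication.

The recipe is an RFC-4122 name-based (version 5) UUID: SHA-1 over a fixed
namespace UUID concatenated with a canonical key string, truncated to 128 bits
with version/variant bits forced.  The canonical key string joins the asset
kind and its normalized components with an ASCII unit separator; separator and
escape characters occurring inside components are escaped first, so distinct
component lists can never collapse onto one key string.
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InvalidKeyError, UnknownKindError

#: Fixed, instance-independent namespace. Deliberately NOT derived from any
#: per-deployment value so archives keyed here can migrate between stores
#: without re-identification.
NAMESPACE = uuid.UUID("7a5a62a9-3b59-4d2e-9f14-c8e14907b001")

#: ASCII unit separator used to join kind and components in the canonical key.
_SEP = "\x1f"
_ESC = "\\"

#: Asset kinds known to the identifier subsystem. Extendable at run time via
#: :func:`register_kind`; deriving an id for an unknown kind is an error so
#: that typos cannot mint parallel identifier spaces.
_REGISTERED_KINDS: set[str] = {
    "dicomArchive",
    "image",
    "outputCollection",
    "file",
}


def register_kind(kind: str) -> None:
    """Register a new asset kind usable in :class:`AssetKey`."""
    if not kind or not kind.strip():
        raise InvalidKeyError("asset kind must be a non-empty string")
    _REGISTERED_KINDS.add(kind)


def registered_kinds() -> frozenset[str]:
    return frozenset(_REGISTERED_KINDS)


@dataclass(frozen=True, order=True)
class DUuid:
    """A deterministic 128-bit identifier.

    The canonical rendering is exactly 36 characters: 32 lowercase hex digits
    in 8-4-4-4-12 groups with four hyphens.
    """

    value: int

    def __post_init__(self) -> None:
        if not 0 <= self.value < 1 << 128:
            raise InvalidKeyError(f"identifier out of 128-bit range: {self.value}")

    def render(self) -> str:
        return str(uuid.UUID(int=self.value))

    def __str__(self) -> str:  # pragma: no cover - convenience alias
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "DUuid":
        try:
            return cls(uuid.UUID(text.strip()).int)
        except (ValueError, AttributeError) as exc:
            raise InvalidKeyError(f"not a canonical identifier: {text!r}") from exc


def _escape(component: str) -> str:
    return component.replace(_ESC, _ESC + _ESC).replace(_SEP, _ESC + "u001f")


def _normalize(component: str) -> str:
    return _escape(component.strip())


@dataclass(frozen=True)
class AssetKey:
    """The identity-bearing description of an asset.

    ``kind`` names the asset class (``dicomArchive``, ``image``, ...);
    ``components`` is the ordered list of strings that determine the asset —
    typically content checksums, or an activity signature plus input ids.
    """

    kind: str
    components: tuple[str, ...] = field(default_factory=tuple)

    def __init__(self, kind: str, components: Iterable[str]):
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "components", tuple(components))

    def canonical_string(self) -> str:
        if self.kind not in _REGISTERED_KINDS:
            raise UnknownKindError(f"unregistered asset kind: {self.kind!r}")
        if not self.components:
            raise InvalidKeyError("asset key needs at least one component")
        normalized = [_normalize(c) for c in self.components]
        if any(not c for c in normalized):
            raise InvalidKeyError("asset key components must be non-empty")
        return _SEP.join([self.kind, *normalized])


def derive_id(key: AssetKey) -> DUuid:
    """Derive the deterministic identifier for an asset key.

    Name-based v5 UUID over :data:`NAMESPACE` and the canonical key string.
    """
    return DUuid(uuid.uuid5(NAMESPACE, key.canonical_string()).int)


def derive_output_id(
    activity_name: str,
    version: str,
    parameters: str,
    input_ids: Sequence[DUuid],
) -> DUuid:
    """Identifier for the output collection of one activity invocation.

    The key is (activity name, version, parameters, sorted input ids): the
    version is part of the computation, so outputs of successive tool releases
    on the same inputs get distinct identifiers, while the order in which
    inputs were listed is irrelevant.
    """
    if not activity_name.strip():
        raise InvalidKeyError("activity name must be non-empty")
    if not version.strip():
        raise InvalidKeyError("activity version must be non-empty")
    if not input_ids:
        raise InvalidKeyError("output identifier requires at least one input id")
    rendered = sorted(i.render() for i in input_ids)
    # parameters may legitimately be empty; keep a placeholder so the key
    # shape stays fixed-length and unambiguous.
    params = parameters if parameters.strip() else "-"
    key = AssetKey("outputCollection", [activity_name, version, params, *rendered])
    return derive_id(key)
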