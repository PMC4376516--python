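"""Keyed one-way record identifiers ("CARES IDs") and the decrypt bridge.

Every record loaded onto the hub is keyed by a CARES ID: a deterministic,
keyed, one-way transformation of the source collection's own unique record
identifier.  The transformation is an HMAC-SHA256 under a per-collection
secret, truncated to a fixed-width 32-hex-character token.  Loading therefore
*encrypts* but nothing on the hub can *decrypt*: no API in the hub or
extraction modules maps a CARES ID back to a source UID.

The only way back is the bridge: the authority holding the linkage-officer
role may look tokens up in an escrowed forward mapping recorded at load time.
Reversal therefore requires BOTH the escrow store and the linkage-officer
role, and every bridge call is written to the audit log.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
from dataclasses import dataclass, field

from .errors import (
    AuthorisationError,
    ConfigurationError,
    InvalidParameterError,
    NotFoundError,
)

#: fixed width of the printable token, in hex characters (128 bits)
TOKEN_LENGTH = 32

#: role required to invoke the bridge
LINKAGE_OFFICER_ROLE = "linkage-officer"


@dataclass(frozen=True)
class CaresId:
    """A one-way encrypted record identifier, scoped to one collection."""

    value: str
    collection_id: str

    def __post_init__(self) -> None:
        if len(self.value) != TOKEN_LENGTH:
            raise InvalidParameterError(
                f"CARES ID token must be {TOKEN_LENGTH} hex chars, "
                f"got {len(self.value)}"
            )


@dataclass(frozen=True)
class CollectionKey:
    """Per-collection secret key material.

    The material never appears in ``repr``/``str`` and is never serialised
    into hub tables, extracts, QA reports or logs; it travels only through
    dedicated key files (:func:`write_key_file`).
    """

    collection_id: str
    material: bytes = field(repr=False)
    holder: str = "custodian"

    def __post_init__(self) -> None:
        if not self.material:
            raise ConfigurationError("collection key material must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"CollectionKey(collection_id={self.collection_id!r}, material=<redacted>)"


def generate_collection_key(
    collection_id: str, seed: int | None = None, holder: str = "custodian"
) -> CollectionKey:
    """Create a 32-byte collection key.

    With ``seed`` the key is a deterministic function of (collection_id, seed)
    so that synthetic environments are reproducible; without it, key material
    comes from the OS entropy pool.
    """
    if seed is None:
        import secrets

        material = secrets.token_bytes(32)
    else:
        material = hashlib.sha256(
            f"collection-key|{collection_id}|{seed}".encode()
        ).digest()
    return CollectionKey(collection_id=collection_id, material=material, holder=holder)


def encrypt_id(collection_id: str, source_uid: str, key: CollectionKey) -> CaresId:
    """One-way encrypt a source record UID into a CARES ID.

    Deterministic: the same (collection, UID, key) always yields the same
    token, so repeated loads of the same record converge on one hub row and
    tokens persisted in one session match tokens recomputed in another.
    """
    if key.collection_id != collection_id:
        raise AuthorisationError(
            f"key for collection {key.collection_id!r} cannot encrypt IDs "
            f"of collection {collection_id!r}"
        )
    if not source_uid:
        raise InvalidParameterError("source_uid must be non-empty")
    digest = hmac.new(
        key.material, f"{collection_id}|{source_uid}".encode(), hashlib.sha256
    ).hexdigest()
    return CaresId(value=digest[:TOKEN_LENGTH], collection_id=collection_id)


class KeyEscrow:
    """Forward mapping CARES ID -> source UID, held by the bridge authority.

    Populated at load time (the only moment the clear source UID and its token
    coexist) and kept apart from the hub: removing the escrow makes the
    mapping unrecoverable even for linkage officers.
    """

    def __init__(self) -> None:
        self._forward: dict[str, dict[str, str]] = {}

    def record(self, cares_id: CaresId, source_uid: str) -> None:
        self._forward.setdefault(cares_id.collection_id, {})[cares_id.value] = source_uid

    def has_collection(self, collection_id: str) -> bool:
        return collection_id in self._forward

    def lookup(self, cares_id: CaresId) -> str:
        try:
            return self._forward[cares_id.collection_id][cares_id.value]
        except KeyError:
            raise NotFoundError(
                f"no escrowed mapping for {cares_id.value} "
                f"(collection {cares_id.collection_id})"
            ) from None

    def __len__(self) -> int:
        return sum(len(m) for m in self._forward.values())


def bridge_decrypt(
    authority,
    cares_ids: list[CaresId],
    key_escrow: KeyEscrow | None,
    audit_log=None,
) -> dict[CaresId, str]:
    """Decrypt CARES IDs back to source UIDs via the escrowed mapping.

    ``authority`` is any user object exposing ``user_id`` and ``roles``; it
    must hold the linkage-officer role.  This is the security property, not a
    convenience: ordinary hub users cannot cross the bridge.  Every call —
    including an empty one — is audited with the caller identity and count.

    Raises
    ------
    AuthorisationError
        if the caller lacks the linkage-officer role.
    ConfigurationError
        if no escrow store is available.
    NotFoundError
        listing every token with no escrowed mapping.
    """
    if LINKAGE_OFFICER_ROLE not in getattr(authority, "roles", ()):
        if audit_log is not None:
            audit_log.append(
                actor=getattr(authority, "user_id", "<unknown>"),
                action="bridge-decrypt",
                subject=f"{len(cares_ids)} ids",
                outcome="deny:not-linkage-officer",
            )
        raise AuthorisationError(
            "bridge decryption requires the linkage-officer role"
        )
    if key_escrow is None:
        raise ConfigurationError("no escrow store available; bridge cannot decrypt")

    missing = [
        cid for cid in cares_ids
        if not key_escrow.has_collection(cid.collection_id)
    ]
    if missing:
        raise ConfigurationError(
            "no escrowed mapping for collection(s): "
            + ", ".join(sorted({c.collection_id for c in missing}))
        )

    result: dict[CaresId, str] = {}
    failures: list[str] = []
    for cid in cares_ids:
        try:
            result[cid] = key_escrow.lookup(cid)
        except NotFoundError:
            failures.append(cid.value)
    if failures:
        raise NotFoundError(
            "unknown CARES ID(s): " + ", ".join(sorted(failures))
        )
    if audit_log is not None:
        audit_log.append(
            actor=authority.user_id,
            action="bridge-decrypt",
            subject=f"{len(cares_ids)} ids",
            outcome="ok",
        )
    return result


# -- key file serialisation ---------------------------------------------------
# Key files are structured text, stored apart from hub tables (never in the
# same directory as loaded data).  Recommended permissions: 0600.

def write_key_file(key: CollectionKey, path) -> None:
    encoded = base64.b64encode(key.material).decode("ascii")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# CARES collection key file — keep separate from hub data\n")
        fh.write(f"collection_id: {key.collection_id}\n")
        fh.write(f"holder: {key.holder}\n")
        fh.write(f"material_b64: {encoded}\n")


def read_key_file(path) -> CollectionKey:
    fields: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, value = line.partition(":")
            fields[name.strip()] = value.strip()
    try:
        return CollectionKey(
            collection_id=fields["collection_id"],
            material=base64.b64decode(fields["material_b64"]),
            holder=fields.get("holder", "custodian"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"key file {path} missing field {exc}") from None
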