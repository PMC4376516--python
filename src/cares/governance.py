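"""Three-tier access governance, project workspaces and the audit log.

Access to any collection for any task requires, in this fixed order:

1. a signed confidentiality agreement (on or before the access date),
2. an unexpired dataset access grant from the collection's custodian
   (valid through ``expires_on`` *inclusive*), and
3. a custodian approval for the task's use of that collection (evidence may
   be informal, e.g. an email of confirmation, and is stored with the task).

Denials report the *first* failing tier so decisions are deterministic and
auditable.  Default posture is deny: a fresh user with no grants is denied on
every collection.  Decisions are evaluated from the registry at call time —
revoking a grant takes effect on the next check, with no caching.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import itertools
from dataclasses import dataclass, field

from .errors import (
    AuthenticationError,
    AuthorisationError,
    ConflictError,
    InvalidParameterError,
    NotFoundError,
)

ROLES = frozenset(
    {"cares-user", "linkage-officer", "custodian", "client-services-analyst"}
)

DENY_REASONS = (
    "no-confidentiality",
    "no-dataset-grant",
    "grant-expired",
    "no-task-approval",
)


@dataclass(frozen=True)
class User:
    user_id: str
    roles: frozenset[str]
    confidentiality_signed: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.roles:
            raise InvalidParameterError("user must hold at least one role")
        unknown = set(self.roles) - ROLES
        if unknown:
            raise InvalidParameterError(f"unknown role(s): {sorted(unknown)}")


@dataclass(frozen=True)
class AccessGrant:
    user_id: str
    collection_id: str
    granted_by: str
    granted_on: _dt.date
    expires_on: _dt.date | None = None


@dataclass(frozen=True)
class TaskApproval:
    task_id: str
    collection_id: str
    approved_by: str
    evidence: str
    approved_on: _dt.date


@dataclass(frozen=True)
class AuditEvent:
    sequence: int
    timestamp: _dt.datetime
    actor: str
    action: str
    subject: str
    outcome: str


@dataclass(frozen=True)
class Decision:
    allowed: bool
    reason: str | None = None  # one of DENY_REASONS when not allowed

    def __bool__(self) -> bool:
        return self.allowed


ALLOW = Decision(True)


class AuditLog:
    """Append-only event log with strictly increasing, gap-free sequence
    numbers; ``verify`` detects any deletion or reordering."""

    def __init__(self) -> None:
        self._events: list[AuditEvent] = []

    @property
    def events(self) -> tuple[AuditEvent, ...]:
        return tuple(self._events)

    def append(self, actor: str, action: str, subject: str, outcome: str) -> AuditEvent:
        event = AuditEvent(
            sequence=len(self._events) + 1,
            timestamp=_dt.datetime.now(_dt.timezone.utc),
            actor=actor,
            action=action,
            subject=subject,
            outcome=outcome,
        )
        self._events.append(event)
        return event

    def verify(self, events=None) -> int | None:
        """Return None if the log is intact, else the first broken position
        (1-based expected sequence number)."""
        seq = [e.sequence for e in (self._events if events is None else events)]
        for position, value in enumerate(seq, start=1):
            if value != position:
                return position
        return None

    def count(self, action: str | None = None) -> int:
        if action is None:
            return len(self._events)
        return sum(1 for e in self._events if e.action == action)

    def __len__(self) -> int:
        return len(self._events)


@dataclass
class Workspace:
    """A per-task working folder readable only by its approved users."""

    task_id: str
    approved_users: set[str]
    contents: dict[str, bytes] = field(default_factory=dict)


def _hash_password(password: str, salt: str) -> str:
    return hashlib.sha256(f"{salt}|{password}".encode()).hexdigest()


class GovernanceRegistry:
    """Registry of users, collections, tasks, grants, approvals and
    workspaces, with every decision audited."""

    def __init__(self, audit: AuditLog | None = None) -> None:
        self.audit = audit if audit is not None else AuditLog()
        self._users: dict[str, User] = {}
        self._passwords: dict[str, tuple[str, str]] = {}  # user_id -> (salt, hash)
        self._collections: set[str] = set()
        self._tasks: set[str] = set()
        self._grants: list[AccessGrant] = []
        self._approvals: list[TaskApproval] = []
        self._workspaces: dict[str, Workspace] = {}
        self._salt_counter = itertools.count()

    # -- registration ---------------------------------------------------

    def register_user(self, user: User, password: str | None = None) -> None:
        if user.user_id in self._users:
            raise ConflictError(f"user {user.user_id!r} already registered")
        self._users[user.user_id] = user
        if password is not None:
            salt = f"s{next(self._salt_counter)}"
            self._passwords[user.user_id] = (salt, _hash_password(password, salt))

    def get_user(self, user_id: str) -> User:
        try:
            return self._users[user_id]
        except KeyError:
            raise NotFoundError(f"unknown user {user_id!r}") from None

    def register_collection_id(self, collection_id: str) -> None:
        self._collections.add(collection_id)

    def register_task(self, task_id: str) -> None:
        self._tasks.add(task_id)

    # -- credentials ----------------------------------------------------

    def verify_password(self, user_id: str, password: str) -> bool:
        """Constant shape for unknown user vs wrong password: both False."""
        entry = self._passwords.get(user_id)
        if entry is None:
            return False
        salt, expected = entry
        return _hash_password(password, salt) == expected

    # -- grants & approvals --------------------------------------------

    def grant_access(self, grant: AccessGrant) -> None:
        granter = self.get_user(grant.granted_by)
        if "custodian" not in granter.roles:
            raise AuthorisationError(
                f"{grant.granted_by!r} is not a custodian and cannot grant access"
            )
        self.get_user(grant.user_id)
        self._grants.append(grant)
        self.audit.append(
            actor=grant.granted_by,
            action="grant-access",
            subject=f"{grant.user_id}:{grant.collection_id}",
            outcome="ok",
        )

    def revoke_access(self, user_id: str, collection_id: str) -> int:
        """Remove all grants for (user, collection); returns number removed."""
        before = len(self._grants)
        self._grants = [
            g
            for g in self._grants
            if not (g.user_id == user_id and g.collection_id == collection_id)
        ]
        removed = before - len(self._grants)
        self.audit.append(
            actor="<registry>",
            action="revoke-access",
            subject=f"{user_id}:{collection_id}",
            outcome=f"removed:{removed}",
        )
        return removed

    def approve_task(self, approval: TaskApproval) -> None:
        approver = self.get_user(approval.approved_by)
        if "custodian" not in approver.roles:
            raise AuthorisationError(
                f"{approval.approved_by!r} is not a custodian and cannot approve tasks"
            )
        self._tasks.add(approval.task_id)
        self._approvals.append(approval)
        self.audit.append(
            actor=approval.approved_by,
            action="approve-task",
            subject=f"{approval.task_id}:{approval.collection_id}",
            outcome="ok",
        )

    # -- the three-tier check ------------------------------------------

    def check_access(
        self,
        user,
        collection_id: str,
        task_id: str,
        on_date: _dt.date,
    ) -> Decision:
        """Evaluate the three tiers in fixed order; audit the decision.

        ``user`` may be a user_id or a :class:`User`.  Unknown user,
        collection or task raises :class:`NotFoundError` (a lookup failure,
        distinct from a deny decision).
        """
        user_id = user.user_id if isinstance(user, User) else user
        user_obj = self.get_user(user_id)
        if collection_id not in self._collections:
            raise NotFoundError(f"unknown collection {collection_id!r}")
        if task_id not in self._tasks:
            raise NotFoundError(f"unknown task {task_id!r}")

        decision = self._evaluate(user_obj, collection_id, task_id, on_date)
        self.audit.append(
            actor=user_id,
            action="access-decision",
            subject=f"{collection_id}:{task_id}",
            outcome="allow" if decision.allowed else f"deny:{decision.reason}",
        )
        return decision

    def _evaluate(
        self, user: User, collection_id: str, task_id: str, on_date: _dt.date
    ) -> Decision:
        # tier 1: confidentiality agreement
        if user.confidentiality_signed is None or user.confidentiality_signed > on_date:
            return Decision(False, "no-confidentiality")
        # tier 2: dataset access grant (valid through expires_on inclusive)
        grants = [
            g
            for g in self._grants
            if g.user_id == user.user_id
            and g.collection_id == collection_id
            and g.granted_on <= on_date
        ]
        if not grants:
            return Decision(False, "no-dataset-grant")
        if not any(g.expires_on is None or on_date <= g.expires_on for g in grants):
            return Decision(False, "grant-expired")
        # tier 3: task approval
        if not any(
            a.task_id == task_id and a.collection_id == collection_id
            for a in self._approvals
        ):
            return Decision(False, "no-task-approval")
        return ALLOW

    # -- project workspaces --------------------------------------------

    def create_workspace(self, task_id: str, approved_users: set[str]) -> Workspace:
        if task_id not in self._tasks:
            raise NotFoundError(f"unknown task {task_id!r}")
        ws = Workspace(task_id=task_id, approved_users=set(approved_users))
        self._workspaces[task_id] = ws
        return ws

    def workspace_put(self, user, workspace: Workspace, name: str, payload: bytes) -> None:
        self._workspace_gate(user, workspace, "workspace-write", name)
        workspace.contents[name] = payload

    def workspace_read(self, user, workspace: Workspace) -> dict[str, bytes]:
        self._workspace_gate(user, workspace, "workspace-read", "<all>")
        return dict(workspace.contents)

    def _workspace_gate(self, user, workspace: Workspace, action: str, subject: str) -> None:
        user_id = user.user_id if isinstance(user, User) else user
        allowed = user_id in workspace.approved_users
        self.audit.append(
            actor=user_id,
            action=action,
            subject=f"{workspace.task_id}:{subject}",
            outcome="ok" if allowed else "deny",
        )
        if not allowed:
            raise AuthorisationError(
                f"user {user_id!r} is not approved for task {workspace.task_id!r}"
            )


def authenticate_user(registry: GovernanceRegistry, user_id: str, password: str) -> User:
    """Verify credentials against the local registry.

    The failure message is identical for an unknown user and a wrong
    password, so callers cannot enumerate accounts.
    """
    ok = registry.verify_password(user_id, password)
    registry.audit.append(
        actor=user_id,
        action="authenticate",
        subject="login",
        outcome="ok" if ok else "deny",
    )
    if not ok:
        raise AuthenticationError("invalid credentials")
    return registry.get_user(user_id)
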