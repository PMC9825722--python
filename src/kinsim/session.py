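"""Sessions, keyed multi-model collections and state snapshots.

A :class:`Session` couples a model IR with its compiled evaluator and the
integrator options, exposes the direct editing API with ``force_regenerate``
control, and serializes its full simulator state — IR, state vector, clock,
globals, trigger flags, RNG state — into a versioned, checksummed snapshot
blob.  Snapshots are portable (canonical JSON inside a small binary frame)
rather than platform-specific, and back the pickle protocol so sessions can
cross process boundaries for parallel work.

:class:`ModelMap` loads a batch of sources on a worker pool into a keyed,
deterministically ordered collection; per-source failures are recorded as
diagnostics without aborting the batch, and results are independent of the
worker count.
"""

from __future__ import annotations

import hashlib
import json
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from . import engine, sbml_io
from .errors import KinsimError, SnapshotError, StaleModelError
from .model_ir import ModelIR
from .simulate import IntegratorOptions, TimeCourse, simulate

__all__ = ["Session", "StateSnapshot", "ModelMap", "load_many"]

_MAGIC = b"KSIM"
_FORMAT_VERSION = 1


@dataclass
class StateSnapshot:
    data: bytes
    format_version: int
    content_hash: str

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.data)

    @classmethod
    def from_file(cls, path) -> "StateSnapshot":
        with open(path, "rb") as fh:
            data = fh.read()
        version, digest = _parse_frame(data)
        return cls(data, version, digest)


def _parse_frame(data: bytes):
    if len(data) < len(_MAGIC) + 1 + 32 or data[:len(_MAGIC)] != _MAGIC:
        raise SnapshotError("not a kinsim state snapshot")
    version = data[len(_MAGIC)]
    digest = data[len(_MAGIC) + 1:len(_MAGIC) + 33]
    payload = data[len(_MAGIC) + 33:]
    if hashlib.sha256(payload).digest() != digest:
        raise SnapshotError("snapshot checksum mismatch")
    if version != _FORMAT_VERSION:
        raise SnapshotError(f"unsupported snapshot format version {version}")
    return version, digest.hex()


class Session:
    """One loaded model: IR + compiled evaluator + integrator options."""

    def __init__(self, ir: ModelIR, seed: int = 0,
                 options: IntegratorOptions | None = None,
                 compile_now: bool = True):
        self.ir = ir
        self.seed = int(seed)
        self.options = options or IntegratorOptions()
        self._exec: engine.ExecutableModel | None = None
        if compile_now:
            self.regenerate()

    # -- loading --------------------------------------------------------
    @classmethod
    def from_source(cls, source, fmt: str | None = None, seed: int = 0,
                    options: IntegratorOptions | None = None) -> "Session":
        return cls(sbml_io.load_model(source, fmt), seed=seed, options=options)

    @property
    def exec(self) -> engine.ExecutableModel:
        if self._exec is None:
            raise StaleModelError("session has no compiled model; call regenerate()")
        return self._exec

    @property
    def stale(self) -> bool:
        return self._exec is None or self._exec.stale

    def regenerate(self, force: bool = False) -> "Session":
        self._exec = engine.compile_model(self.ir, force_regenerate=force,
                                          seed=self.seed)
        return self

    def _after_edit(self, force_regenerate: bool):
        if force_regenerate:
            self.regenerate()

    # -- direct API -----------------------------------------------------
    def add_species(self, id_, compartment, init_value=0.0,
                    is_concentration=True, boundary=False, constant=False,
                    force_regenerate: bool = True):
        self.ir.add_species(id_, compartment, init_value, is_concentration,
                            boundary, constant)
        self._after_edit(force_regenerate)
        return self

    def add_reaction(self, id_, reactants, products, rate_law,
                     reversible=True, force_regenerate: bool = True):
        self.ir.add_reaction(id_, reactants, products, rate_law, reversible)
        self._after_edit(force_regenerate)
        return self

    def add_compartment(self, id_, size=1.0, constant=True,
                        force_regenerate: bool = True):
        self.ir.add_compartment(id_, size, constant)
        self._after_edit(force_regenerate)
        return self

    def add_parameter(self, id_, value=0.0, constant=True,
                      force_regenerate: bool = True):
        self.ir.add_parameter(id_, value, constant)
        self._after_edit(force_regenerate)
        return self

    def add_event(self, id_, trigger, assignments, force_regenerate: bool = True):
        self.ir.add_event(id_, trigger, assignments)
        self._after_edit(force_regenerate)
        return self

    def remove_component(self, id_, cascade=False, force_regenerate: bool = True):
        self.ir.remove_component(id_, cascade=cascade)
        self._after_edit(force_regenerate)
        return self

    # -- simulation convenience ------------------------------------------
    def simulate(self, start, end, points, opts: IntegratorOptions | None = None,
                 species=None) -> TimeCourse:
        return simulate(self.exec, start, end, points, opts or self.options,
                        species=species)

    def reset(self) -> "Session":
        self.exec.reset()
        return self

    # -- snapshots -------------------------------------------------------
    def save_state(self, path=None) -> StateSnapshot:
        """Capture IR, state vector, clock, globals, options and RNG state."""
        xm = self.exec  # raises if stale / uncompiled
        if xm.stale:
            raise StaleModelError("cannot snapshot a stale session")
        payload = {
            "ir": self.ir.to_dict(),
            "seed": self.seed,
            "state": xm.state.tolist(),
            "g": xm.g.tolist(),
            "time": xm.time,
            "trigger_state": list(xm.trigger_state),
            "rng_state": xm.rng.bit_generator.state,
            "options": self.options.to_dict(),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        digest = hashlib.sha256(blob).digest()
        data = _MAGIC + bytes([_FORMAT_VERSION]) + digest + blob
        snap = StateSnapshot(data, _FORMAT_VERSION, digest.hex())
        if path is not None:
            snap.save(path)
        return snap

    @classmethod
    def load_state(cls, snapshot) -> "Session":
        """Restore a session from a snapshot (object, bytes, or file path).

        Loading reuses the compiled-artifact cache, so it is cheaper than a
        fresh compile whenever the same model structure was seen before.
        """
        if isinstance(snapshot, (str, os.PathLike)):
            snapshot = StateSnapshot.from_file(snapshot)
        elif isinstance(snapshot, bytes):
            version, digest = _parse_frame(snapshot)
            snapshot = StateSnapshot(snapshot, version, digest)
        _parse_frame(snapshot.data)  # validates magic, version, checksum
        payload = json.loads(snapshot.data[len(_MAGIC) + 33:])
        ir = ModelIR.from_dict(payload["ir"])
        sess = cls(ir, seed=payload["seed"],
                   options=IntegratorOptions.from_dict(payload["options"]))
        xm = sess.exec
        xm.state = np.array(payload["state"], dtype=float)
        xm.g = np.array(payload["g"], dtype=float)
        xm.time = float(payload["time"])
        xm.trigger_state = [bool(b) for b in payload["trigger_state"]]
        xm.rng.bit_generator.state = payload["rng_state"]
        return sess

    # -- pickle protocol -------------------------------------------------
    def __reduce__(self):
        return (_restore_session, (self.save_state().data,))


def _restore_session(blob: bytes) -> Session:
    return Session.load_state(blob)


class ModelMap:
    """Keyed collection of sessions, loaded in parallel.

    Keys come from the model's id attribute, falling back to the source file
    stem and finally an index suffix on collision.  Iteration order is sorted
    by key and all observable behaviour is independent of ``workers``.
    """

    def __init__(self, sources, workers: int = 1, seed: int = 0):
        if workers < 1:
            raise ValueError("workers must be >= 1")
        self.workers = int(workers)
        self.diagnostics: dict[str, str] = {}
        self._entries: dict[str, Session] = {}

        prepared = []
        for idx, src in enumerate(sources):
            prepared.append((idx, src))

        def load(item):
            idx, src = item
            try:
                if isinstance(src, ModelIR):
                    ir = src.copy()
                else:
                    ir = sbml_io.load_model(src)
                return idx, src, Session(ir, seed=seed), None
            except Exception as err:  # record, never abort the batch
                return idx, src, None, f"{type(err).__name__}: {err}"

        if self.workers == 1:
            results = [load(item) for item in prepared]
        else:
            with ThreadPoolExecutor(max_workers=self.workers) as pool:
                results = list(pool.map(load, prepared))

        for idx, src, sess, error in sorted(results, key=lambda r: r[0]):
            key = self._make_key(idx, src, sess)
            if error is not None:
                self.diagnostics[key] = error
            else:
                self._entries[key] = sess

    def _make_key(self, idx, src, sess) -> str:
        key = None
        if sess is not None and sess.ir.id and sess.ir.id != "model":
            key = sess.ir.id
        if key is None and isinstance(src, (str, os.PathLike)) \
                and not str(src).lstrip().startswith("<") and os.path.exists(str(src)):
            key = os.path.splitext(os.path.basename(str(src)))[0]
        if key is None:
            key = f"model_{idx}"
        if key in self._entries or key in self.diagnostics:
            key = f"{key}_{idx}"
        return key

    def keys(self):
        return sorted(self._entries)

    def __iter__(self):
        return iter(self.keys())

    def __len__(self):
        return len(self._entries)

    def __contains__(self, key):
        return key in self._entries

    def __getitem__(self, key) -> Session:
        return self._entries[key]

    def items(self):
        return [(k, self._entries[k]) for k in self.keys()]

    def values(self):
        return [self._entries[k] for k in self.keys()]


def load_many(sources, workers: int = 1, seed: int = 0) -> ModelMap:
    """Compile a collection of SBML files/strings (or IRs) in parallel."""
    return ModelMap(sources, workers=workers, seed=seed)
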