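"""Simulated federated training: sharding, FedAvg / server-optimizer aggregation.

One *round* broadcasts the global weights W_r to every client, trains locally
on each client's shard, and aggregates the returned weights.  *simple*
aggregation is the sample-size-weighted average W_{r+1} = sum_c (S_c / S) W_r^c
(FedAvg).  *opt* aggregation treats the discrepancy between the global model
and that average as a pseudo-gradient, Delta_r = W_r - avg_c, and applies a
server-side optimizer step to it; with plain gradient descent at server step
1.0 it reduces exactly to the simple rule.

Transport is in-process by default; a length-prefixed socket protocol over
localhost mirrors the client/server deployment architecture.
"""

from __future__ import annotations

import dataclasses
import io
import socket
import struct
import threading
from typing import Sequence

import numpy as np

from . import lstm
from ._rng import child_rng

Weights = dict[str, np.ndarray]


@dataclasses.dataclass
class ClientUpdate:
    client_id: int
    weights: Weights
    n_samples: int

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("client sample size must be >= 1")


@dataclasses.dataclass
class ServerState:
    weights: Weights
    round: int = 0
    aggregation: str = "simple"
    server_lr: float = 1.0
    server_optimizer: str = "sgd"  # "sgd" | "adam"
    _adam_m: Weights | None = None
    _adam_v: Weights | None = None
    _adam_t: int = 0


@dataclasses.dataclass(frozen=True)
class FederationConfig:
    n_clients: int = 2
    n_rounds: int = 5
    local: lstm.TrainConfig = dataclasses.field(default_factory=lstm.TrainConfig)
    aggregation: str = "simple"
    server_lr: float = 1.0
    server_optimizer: str = "sgd"
    transport: str = "in_process"
    seed: int = 0

    def __post_init__(self):
        if self.n_clients < 1 or self.n_rounds < 1:
            raise ValueError("n_clients and n_rounds must be >= 1")
        if self.aggregation not in ("simple", "opt"):
            raise ValueError("aggregation must be 'simple' or 'opt'")


def shard_training_data(grids: Sequence, n_clients: int, seed: int = 0) -> list[list]:
    """Disjoint, exhaustive shards whose sizes differ by at most one."""
    if n_clients > len(grids):
        raise ValueError(f"cannot shard {len(grids)} episodes over {n_clients} clients")
    rng = child_rng(seed, "shard")
    order = rng.permutation(len(grids))
    return [
        [grids[i] for i in chunk] for chunk in np.array_split(order, n_clients)
    ]


def _weighted_average(updates: Sequence[ClientUpdate]) -> Weights:
    total = sum(u.n_samples for u in updates)
    if total <= 0:
        raise ValueError("total client sample size must be positive")
    keys = updates[0].weights.keys()
    avg: Weights = {}
    for k in keys:
        avg[k] = sum((u.n_samples / total) * u.weights[k] for u in updates)
    return avg


def aggregate_simple(updates: Sequence[ClientUpdate]) -> Weights:
    """FedAvg: element-wise average weighted by client sample sizes S_c / S."""
    if not updates:
        raise ValueError("no client updates to aggregate")
    return _weighted_average(updates)


def aggregate_opt(server: ServerState, updates: Sequence[ClientUpdate]) -> Weights:
    """Server-optimizer step on the pseudo-gradient W_r - weighted_average(updates)."""
    avg = _weighted_average(updates)
    delta = {k: server.weights[k] - avg[k] for k in avg}
    if server.server_optimizer == "sgd":
        return {k: server.weights[k] - server.server_lr * delta[k] for k in avg}
    if server.server_optimizer != "adam":
        raise ValueError("server_optimizer must be 'sgd' or 'adam'")
    b1, b2, eps = 0.9, 0.999, 1e-8
    if server._adam_m is None:
        server._adam_m = {k: np.zeros_like(v) for k, v in delta.items()}
        server._adam_v = {k: np.zeros_like(v) for k, v in delta.items()}
    server._adam_t += 1
    t = server._adam_t
    out: Weights = {}
    for k, g in delta.items():
        server._adam_m[k] = b1 * server._adam_m[k] + (1 - b1) * g
        server._adam_v[k] = b2 * server._adam_v[k] + (1 - b2) * g * g
        mhat = server._adam_m[k] / (1 - b1**t)
        vhat = server._adam_v[k] / (1 - b2**t)
        out[k] = server.weights[k] - server.server_lr * mhat / (np.sqrt(vhat) + eps)
    return out


def _client_seed(seed: int, round_index: int, client_index: int) -> int:
    # Deterministic, collision-free derivation kept below 2**31.
    return (seed * 1_000_003 + round_index * 1_009 + client_index) % (2**31 - 1)


def run_federation(
    config: FederationConfig,
    train_grids: Sequence,
    test_grids: Sequence | None = None,
):
    """Full federated simulation; returns (per-round weights, per-round reports).

    Every round trains each client from the broadcast weights over its fixed
    shard, aggregates per the configured rule, and (when a test split is
    given) evaluates the *aggregated* model — never a single client's.
    A client failure aborts the round: no partial aggregation.
    """
    from . import metrics as evalreport

    shards = shard_training_data(train_grids, config.n_clients, seed=config.seed)
    input_dim = train_grids[0].values.shape[1]
    init = lstm.init_params(
        input_dim, config.local, child_rng(config.seed, "fed-init")
    )
    server = ServerState(
        weights=init,
        aggregation=config.aggregation,
        server_lr=config.server_lr,
        server_optimizer=config.server_optimizer,
    )
    round_weights: list[Weights] = []
    reports = []
    for r in range(1, config.n_rounds + 1):
        updates = []
        for c, shard in enumerate(shards):
            try:
                model, _ = lstm.train(
                    shard,
                    config.local,
                    init=server.weights,
                    seed=_client_seed(config.seed, r, c),
                )
            except Exception as exc:
                raise RuntimeError(
                    f"round {r}: client {c} failed ({exc}); aborting round"
                ) from exc
            updates.append(ClientUpdate(c, model.params, len(shard)))
        if config.transport == "socket":
            new_weights = aggregate_over_sockets(updates, server)
        elif config.aggregation == "simple":
            new_weights = aggregate_simple(updates)
        else:
            new_weights = aggregate_opt(server, updates)
        server.weights = new_weights
        server.round = r
        round_weights.append({k: v.copy() for k, v in new_weights.items()})
        if test_grids is not None:
            model = lstm.LstmModel(server.weights, config.local, input_dim)
            traces = lstm.predict_cohort(test_grids, model)
            report = evalreport.report_from_traces(traces, test_grids)
            reports.append(report)
    return round_weights, reports


def centralized_rounds(
    train_grids: Sequence, config: FederationConfig
) -> list[Weights]:
    """Single-machine reference schedule matching a one-client federation."""
    shard = shard_training_data(train_grids, 1, seed=config.seed)[0]
    input_dim = train_grids[0].values.shape[1]
    weights = lstm.init_params(
        input_dim, config.local, child_rng(config.seed, "fed-init")
    )
    out = []
    for r in range(1, config.n_rounds + 1):
        model, _ = lstm.train(
            shard, config.local, init=weights, seed=_client_seed(config.seed, r, 0)
        )
        weights = model.params
        out.append({k: v.copy() for k, v in weights.items()})
    return out


# --- socket transport -------------------------------------------------------

_LEN_FMT = "!Q"


def serialize_weights(weights: Weights) -> bytes:
    buf = io.BytesIO()
    np.savez(buf, **weights)
    return buf.getvalue()


def deserialize_weights(payload: bytes) -> Weights:
    if not payload:
        raise ValueError("empty weight payload")
    with np.load(io.BytesIO(payload)) as data:
        return {k: data[k].copy() for k in data.files}


def send_frame(sock: socket.socket, payload: bytes) -> None:
    if not payload:
        raise ValueError("refusing to send an empty frame")
    sock.sendall(struct.pack(_LEN_FMT, len(payload)) + payload)


def recv_frame(sock: socket.socket) -> bytes:
    header = _recv_exact(sock, struct.calcsize(_LEN_FMT))
    (length,) = struct.unpack(_LEN_FMT, header)
    if length == 0:
        raise ValueError("zero-length frame")
    return _recv_exact(sock, length)


def _recv_exact(sock: socket.socket, n: int) -> bytes:
    chunks = []
    got = 0
    while got < n:
        chunk = sock.recv(n - got)
        if not chunk:
            raise ConnectionError("truncated frame")
        chunks.append(chunk)
        got += len(chunk)
    return b"".join(chunks)


def aggregate_over_sockets(
    updates: Sequence[ClientUpdate], server: ServerState
) -> Weights:
    """Round-trip every update through a localhost socket, then aggregate.

    Exercises the wire protocol while keeping the arithmetic identical to the
    in-process path: weights are bit-identical after serialization.
    """
    received: dict[int, ClientUpdate] = {}
    listener = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
    listener.bind(("127.0.0.1", 0))
    listener.listen(len(updates))
    port = listener.getsockname()[1]
    lock = threading.Lock()

    def serve():
        for _ in range(len(updates)):
            conn, _ = listener.accept()
            with conn:
                meta = recv_frame(conn)
                client_id, n_samples = struct.unpack("!QQ", meta)
                weights = deserialize_weights(recv_frame(conn))
                with lock:
                    received[client_id] = ClientUpdate(client_id, weights, n_samples)
                send_frame(conn, b"ok")

    server_thread = threading.Thread(target=serve)
    server_thread.start()
    for u in updates:
        with socket.create_connection(("127.0.0.1", port)) as conn:
            send_frame(conn, struct.pack("!QQ", u.client_id, u.n_samples))
            send_frame(conn, serialize_weights(u.weights))
            recv_frame(conn)
    server_thread.join()
    listener.close()
    ordered = [received[u.client_id] for u in updates]
    if server.aggregation == "simple":
        return aggregate_simple(ordered)
    return aggregate_opt(server, ordered)
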