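"""Plain-text (YAML) configuration for network parameters, solver settings
and stimulus protocols.  A bundled default config reproduces the fitted
parameter set and the standard adapt-then-test protocol."""

from __future__ import annotations

from importlib import resources

import yaml

from .network import NetworkParams, SolverSettings, StimulusEpoch, StimulusProtocol


def _network_from_dict(d: dict) -> NetworkParams:
    return NetworkParams(**d)


def _solver_from_dict(d: dict) -> SolverSettings:
    return SolverSettings(**d)


def _protocol_from_dict(d: dict) -> StimulusProtocol:
    epochs = tuple(StimulusEpoch(**e) for e in d["epochs"])
    return StimulusProtocol(epochs=epochs, label=d.get("label", ""))


def parse_config(d: dict) -> dict:
    """Turn a parsed config mapping into model objects.

    Recognized sections: ``network`` -> NetworkParams, ``solver`` ->
    SolverSettings, ``protocol`` -> StimulusProtocol.  Missing sections get
    defaults (and None for the protocol).
    """
    return {
        "network": _network_from_dict(d.get("network", {}) or {}),
        "solver": _solver_from_dict(d.get("solver", {}) or {}),
        "protocol": _protocol_from_dict(d["protocol"]) if "protocol" in d else None,
    }


def load_config(path) -> dict:
    """Read a YAML config file; see :func:`parse_config` for the layout."""
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh) or {})


def default_config() -> dict:
    """The bundled default: fitted parameters, standard solver settings and
    the 20° adapter / 0° test protocol."""
    text = resources.files("ringtae").joinpath("data/default_network.yaml").read_text()
    return parse_config(yaml.safe_load(text))
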