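"""Access to the frozen canonical parameter sets.

The neuron parameters were produced by tuning the model family against
the step-response classification protocol (tonic / delayed / single);
the receptive-field parameters by tuning against the center-surround
constraint suite (co-stimulation ratios, zone areas, zone drives).  Both
live in ``data/canonical.yaml`` and are treated as read-only.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .neuron_models import NeuronModel

__all__ = ["canonical_config", "canonical_neuron", "canonical_rf"]


@lru_cache(maxsize=1)
def canonical_config() -> dict:
    text = resources.files("dorsalhorn").joinpath("data/canonical.yaml").read_text()
    return yaml.safe_load(text)


def canonical_neuron(label: str) -> NeuronModel:
    """The frozen model for one cell class.

    ``label`` is a model label (``inhibitory_tonic``, ``excitatory_delayed``,
    ``excitatory_single``) or an in-vivo unit class (``adapting`` maps to
    the delayed-spiking excitatory model, ``non_adapting`` to the
    tonic-spiking inhibitory model).
    """
    alias = {"adapting": "excitatory_delayed", "non_adapting": "inhibitory_tonic"}
    label = alias.get(label, label)
    neurons = canonical_config()["neurons"]
    if label not in neurons:
        raise KeyError(f"no canonical neuron named {label!r}")
    return NeuronModel.from_dict(neurons[label])


def canonical_rf(cell_class: str):
    """The frozen receptive field for ``adapting`` or ``non_adapting``."""
    from .receptive_field import RFSpec

    rfs = canonical_config()["receptive_fields"]
    if cell_class not in rfs:
        raise KeyError(f"no canonical receptive field for class {cell_class!r}")
    d = dict(rfs[cell_class])
    d["center"] = tuple(d["center"])
    return RFSpec(**d)
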