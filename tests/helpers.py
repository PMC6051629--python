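import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))
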