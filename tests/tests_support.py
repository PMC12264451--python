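import numpy as np

from tpenet.graphs import BinaryGraph


def binary_graph_from(A, sparsity=0.5):
    return BinaryGraph(adjacency=np.asarray(A, dtype=np.int8), sparsity=sparsity)
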