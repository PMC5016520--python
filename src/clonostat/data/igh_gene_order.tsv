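# Human IGH locus gene order (3' -> 5' for V, locus position for D and J).
# Approximation of the IMGT/GENE-DB locus ordering, bundled so no network
# lookup is needed; override with a user file where exact order matters.
# columns: group	gene
IGHV	IGHV6-1
IGHV	IGHV1-2
IGHV	IGHV1-3
IGHV	IGHV4-4
IGHV	IGHV7-4-1
IGHV	IGHV2-5
IGHV	IGHV3-7
IGHV	IGHV1-8
IGHV	IGHV3-9
IGHV	IGHV3-11
IGHV	IGHV3-13
IGHV	IGHV3-15
IGHV	IGHV1-18
IGHV	IGHV3-20
IGHV	IGHV3-21
IGHV	IGHV3-23
IGHV	IGHV1-24
IGHV	IGHV2-26
IGHV	IGHV4-28
IGHV	IGHV4-30-2
IGHV	IGHV4-30-4
IGHV	IGHV4-31
IGHV	IGHV4-34
IGHV	IGHV4-39
IGHV	IGHV3-43
IGHV	IGHV1-45
IGHV	IGHV1-46
IGHV	IGHV3-48
IGHV	IGHV3-49
IGHV	IGHV5-51
IGHV	IGHV3-53
IGHV	IGHV1-58
IGHV	IGHV4-59
IGHV	IGHV4-61
IGHV	IGHV3-64
IGHV	IGHV3-66
IGHV	IGHV1-69
IGHV	IGHV2-70
IGHV	IGHV3-72
IGHV	IGHV3-73
IGHV	IGHV3-74
IGHD	IGHD1-1
IGHD	IGHD2-2
IGHD	IGHD3-3
IGHD	IGHD4-4
IGHD	IGHD5-5
IGHD	IGHD6-6
IGHD	IGHD1-7
IGHD	IGHD2-8
IGHD	IGHD3-9
IGHD	IGHD3-10
IGHD	IGHD4-11
IGHD	IGHD5-12
IGHD	IGHD6-13
IGHD	IGHD1-14
IGHD	IGHD2-15
IGHD	IGHD3-16
IGHD	IGHD4-17
IGHD	IGHD5-18
IGHD	IGHD6-19
IGHD	IGHD1-20
IGHD	IGHD2-21
IGHD	IGHD3-22
IGHD	IGHD4-23
IGHD	IGHD5-24
IGHD	IGHD6-25
IGHD	IGHD1-26
IGHD	IGHD7-27
IGHJ	IGHJ1
IGHJ	IGHJ2
IGHJ	IGHJ3
IGHJ	IGHJ4
IGHJ	IGHJ5
IGHJ	IGHJ6
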