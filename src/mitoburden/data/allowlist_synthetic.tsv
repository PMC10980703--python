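# Synthetic stand-in for a curated mtDNA variant allow-list (pos, ref, alt).
# These entries are fabricated for tests and demos; substitute a real
# database export for production use.
pos	ref	alt
73	A	G
195	T	C
263	A	G
750	A	G
1438	A	G
2706	A	G
3243	A	G
4769	A	G
7028	C	T
8860	A	G
10398	A	G
11467	A	G
11719	G	A
11778	G	A
12308	A	G
13708	G	A
14484	T	C
14766	C	T
15326	A	G
16189	T	C
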