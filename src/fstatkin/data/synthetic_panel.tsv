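# synthetic four-population frequency panel; see fstatkin.data docstring
locus	A	B	C	D
L01	0.36455	0.13345	0.6017	0.14895
L02	0.8337	0.711	0.7596	0.8158
L03	0.3853	0.3869	0.09105	0.22875
L04	0.09695	0.11265	0.12475	0.70585
L05	0.7452	0.96235	0.6216	0.9857
L06	0.0095	0.86825	0.32035	0.07545
L07	0.5914	0.15565	0.4852	0.28855
L08	0.4941	0.8005	0.5454	0.37645
L09	0.0385	0.2813	0.29245	0.39705
L10	0.12005	0.17	0.287	0.1755
L11	0.84355	0.66535	0.6808	0.60785
L12	0.40175	0.5318	0.3796	0.10575
L13	0.2864	0.1784	0.4774	0.3452
L14	0.3325	0.5516	0.4022	0.40465
L15	0.7279	0.8313	0.672	0.77095
L16	0.7795	0.739	0.31885	0.5069
L17	0.1005	0.06155	0.11655	0.2709
L18	0.4322	0.5948	0.5293	0.6082
L19	0.9162	0.9015	0.58205	0.398
L20	0.31765	0.5095	0.35825	0.46505
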