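enzyme	substitution	position	csm_label	region	active_site	function_notes
CYP1A2	E163K	163	6-7	D helix	false	Enhanced activity; substrate selectivity
CYP1A2	K170Q	170	7	D helix	false	Enhanced activity; substrate selectivity
CYP1A2	V193M	193	8-9	E helix	false	Enhanced activity; substrate selectivity
CYP1A2	E225N	225	10	F helix	false	Enhanced activity; substrate selectivity
CYP1A2	Q258H	258	11	G helix	false	Enhanced activity; substrate selectivity
CYP1A2	G437D	437	18	K'-L loop	false	Enhanced activity; substrate selectivity
CYP2A6	S183C	183	7-8	E helix	false	Enhanced activity; altered substrate specificity; novel activity
CYP2A6	L206Q	206	8-9	F helix	false	Enhanced activity; altered substrate specificity; novel activity
CYP2A6	F209I	209	8-9	F helix	true	Enhanced activity; altered substrate specificity; novel activity
CYP2A6	S224P	224	9	F-G loop	false	Enhanced activity; altered substrate specificity; novel activity
CYP2A6	L240C	240	10-11	G helix	false	Enhanced activity; altered substrate specificity; novel activity
CYP2A6	Y287H	287	11-12	I helix	false	Enhanced activity; altered substrate specificity; novel activity
CYP2A6	N297Q	297	12	I helix	false	Enhanced activity; altered substrate specificity; novel activity
CYP2A6	I300V	300	12	I helix	false	Enhanced activity; altered substrate specificity; novel activity
CYP2A6	T305S	305	12	I helix	true	Enhanced activity; altered substrate specificity; novel activity
CYP2Bs	V183L	183	7-8	E helix	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP2Bs	F202A	202	8-9	F helix	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP2Bs	L209A	209	8-9	F helix	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP2Bs	K236I	236	10-11	G helix	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP2Bs	D257N	257	10-11	G-H loop	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP2Bs	L264F	264	11	H helix	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP2Bs	L295H	295	12	I helix	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP2Bs	S334P	334	13-14	J-J' loop	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP2Bs	P334S	334	13-14	J-J' loop	false	Enhanced activity; altered substrate specificity; increased protein stability; enhanced tolerance to organic solvents
CYP3A4	L216W	216	8	F helix	false	Enhanced activity; altered substrate specificity
CYP3A4	F228I	228	10	F-G loop	false	Enhanced activity; altered substrate specificity
CYP3A4	T433S	433	17	L helix	false	Enhanced activity; altered substrate specificity
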