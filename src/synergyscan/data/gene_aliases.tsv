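alias	symbol
MCP-2	CCL8
MCP-5	CCL12
MIG	CXCL9
IP-10	CXCL10
IP10	CXCL10
SECTM1A	SECTM1
ETSRP71	ETV2
LINCR	NLRP10
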