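>mcp_synthetic_00 category=MCP synthetic
PKMRAYYMMDILDVAFAPTFGFYSRHWYMWHWHSIHSQLWWSFMQESMNTHELYTYLPEGAYTTSHWSPSCCLFAGWERNKILVDWQSHMVGVQVLACMDQMTGNSCGNKTTVFQQKMFQVTRWC
>mcp_synthetic_01 category=MCP synthetic
PKMREISMMHILDVAFAKTFGFYSSHWYLWIWHSIHSPLWWSFWQESMLMHELYTEAPEGARTTSHWSPSCCLFAGWERNKILVDWQSHMVGVKVQCCNDQHTPNSQGNKTTMFQQFMFQVTRWC
>mcp_synthetic_02 category=MCP synthetic
PKMREYYMMDILDVAFAPTFGFYSSHWYLAHWHSIHSELDFWFMQESMVEHELSTWAPEGGYTTSHWSPLCWQFAGWRRNKILVNEKSHMVGVGVQCCQDQMTGNSCGNKTTMFQQKMFQVTRWC
>mcp_synthetic_03 category=MCP synthetic
PKMREYMMMDILHVAFAPTFVVYSSHWYLWHWHSIHSELPWSQMQESMNEHELKTWAPSGDYTTSHWYPGCCLFAGWERNKILVDWQSHMVGVKVQCCNDQHTGNSCGNRTTMFQQKMFMVTRYC
>mcp_synthetic_04 category=MCP synthetic
PKMREYHMMDILDVAFAPTFESYSSHWYVWHWHMIHSELWWAFYQESMNEHELYTWHPEGAYTTSHWSPSCCLFAGWERNKIIVYWRSHMVGVKVQCCNDQHTGNSGGGKTTMFQQKMFQVTRWI
>mcp_synthetic_05 category=MCP synthetic
PKMREYYMMDILDVAFAPTQGFYSSHWYLWHWHSIHSELWWSFMQESMNEVELYTWAPEGAYTTSHWSPSCCLFTGWERRKILVDWQSHMHGVKVQCCNDQHTGNSCGNYTTMFQQKMFQVTRWA
>mcp_synthetic_06 category=MCP synthetic
PYMREYYMMDILDVAFAPTFGFYLSCWYLWHWHSIHSDLWTSFMQWSMNEHELYTWAPEGAYTTPHWSPSCCLFAGWSRNGILVDWQSHMVGVKKQCCNDQHQGNSCGNKTRMFQQKMFQVTRWC
>mcp_synthetic_07 category=MCP synthetic
PGMRRYCMMDILEVAFAPTFGFCSSHAYLWAMHSIHSELWWNFMAESMKEHELYTWADEGAITTSHWSPPCCLEIGWNRPKILVDWQSHMVGVKHQYCNDQHTGNSCGNKTDMFQQKQFQVWRWI
>mcp_synthetic_08 category=MCP synthetic
PKKREYYMMEILKVKFAPTFCFYASHWYLWHWHSIHSELWWSFMQESMNEHELYTWAPEGAMTTSHVLPSVCLFKGDEWNKILVDWQSHMVGVSVQCCNDQHTGNSCGNKTQMFQQKRFQVTRAC
>mcp_synthetic_09 category=MCP synthetic
PKMREYYMMDILDVAFAPTFVFYSSHWYYWHWHSIHSEFWWSFMEEAMNEHELYLWAPEGAYTTSHWVPMNCLFAGKERNKILVDWQSHMVGVKVQCCGDQHTDNSCGNITTMFQQKMFQVTRWC
>mcp_synthetic_10 category=MCP synthetic
PKMREYYMMDILDVAFHPTFGFYSSHWYLHHWHSVHSELWWSFMQESMNEHELYTWAPGCPYTTNHFSPSHFLFAGWERNKILVDWQSHMVGMKVQRCNDQHTGGSCGNKTTMFQQKMFQMTRWC
>mcp_synthetic_11 category=MCP synthetic
PKEDETYMMDILDVHFAPTFGFYSSIWYNWVWHSIHSELYWSFMYESMNEHELYTWAPEGAYTTEYWGPSCCLFAGWVCNKILVDWQGHMVRVKVQCCNDQHTGNSCGNVQPMDQQKMFQVTRQC
>mcp_synthetic_12 category=MCP synthetic
PEMTEYYMMDILDVAFAETFGFYSSHWYLWHWHSIHSELWWSFMQESMWWHELYTWAPNGAYTTSHWSPSCCLFANWERNEILVDWQSCMVGVKVQCCNDQHYGISCGNKTTMFQQIMFTVTRWC
>mcp_synthetic_13 category=MCP synthetic
PKMREYYMMDILDVAFAPTFGFISSHWYLWHHHHIHSELWWSFMQESCNEHELYTWAPMGAYTTPHWSPSCCLFAGWERNKILVDWQSHMVGVKVQCCNDQHTGNSCGNKTVMFQQKMFQVTHWC
>mcp_synthetic_14 category=MCP synthetic
PYMVGTYMMDIEDVAFAPTFGTYLSHWYLWHWHSIHSILWWSFMQESMDEHILYTWAPEGAYTTSHWSPSCCGFAGWERAKILVSWQSAMVGVKVQCCNDQHTYPSCFNKTTMFQQKMFQVTRWC
>mcp_synthetic_15 category=MCP synthetic
PKMREYYMMDIMDVAFAPTFGFYSSHWYLTHWGSIHSFLWHSFMQESMNEHELYTWAPMGAYTTSHWSASCCLFAGWERNKILYDWSSHMVSVKVQCCNDQHTLNSCGNKTTMFQQKMFQVMRWC
>mcp_synthetic_16 category=MCP synthetic
PKMREYVMMDILDVAFAPTMGFYSSHWYLWHWHSIHSELWWSQMQESDNEHELYTWAPEGAYTTKHWIPSCCLFAGWERNKILVDEQSHMVGVKVQCCNKQHTGNSCGNKEDMFQQKMFQVTINC
>mcp_synthetic_17 category=MCP synthetic
PKMREYYMMDILDVAFRPTFGFYSNHWYLWHWHSIHSELWWSFMQESMNEHELYTWAVEGAYHTSHWSTSCCLFAGWERNKILVDWQSHMEGVKTQCCNDPHTMNSPWNKKTMFQQKMFQVTRWC
>mcp_synthetic_18 category=MCP synthetic
PKKREYYMQDICKVDFAPTYGFYSSHWYLWTWHSIHSEQWYSFYQESQNEHELYTWAPEGAYTTSHYHPSCCLFAAWERNKILVDWQSHMVGVEVSCCNDQHSGNHCGNKQTMFQQKMFQVTFWC
>mcp_synthetic_19 category=MCP synthetic
CKMREYYMMDHLDVAFAPTFGHKSSHWYLWHWHSIHSMLWWSFMQESMNEHELYTWAPSGAYTTSHWSPSCCLTCGWEWNKILVDWQSHMVHVDVMCQNDQHTGNSCGNKTTVFQQKMFQVTRWC
>mcp_synthetic_20 category=MCP synthetic
PKMREKYMMDILDVACTPTFGFISSHWYLGHWHSIHSELWWSFMQESMNEHELYWWAPEGWYTTSHWSPCCCLFAGGERNKILVDWQSHMVGVKVYCCNDMHTGNSCGNKTTMFGQKMFQPTRWC
>mcp_synthetic_21 category=MCP synthetic
PKMREYTMMRILDQAFAPTFGFYSSHWYHWHWHKIHSGLWWHFWQESMNEHELHTWAPEGAYLTSHWSPSCCLFRGCERNKILVDWQSHMVGVKVQCCNDQHHGNSCGNKTTMFQQKMFQVTRWC
>mcp_synthetic_22 category=MCP synthetic
PKMREKYMKYIWYVAFAWTFGFYSSHWYLWHWHSIHPEIFWSFMQESRNEHELYTWAPPGAYTSSHWSPSCCTFAGWERNKILVNWQSHHVGVKVQCCNDPHTGNSCWNKTTMFQQKMFQVTRWC
>mcp_synthetic_23 category=MCP synthetic
PKMREYYMMDILDIAFATTFGFYSSHWYLWHWHSIHSELWWSFMQESMNEHELYTWAPEGAYNTSHWSPSCDAFNGWLRNKILVLWQSHMVGVKVQCCMDQHTGQSCGNKTTMFQQKMFQNWRWC
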