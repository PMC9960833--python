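Code	Scientific Name	Geographic Location	Altitude (Meters)	Latitude	Longitude
A1	Ribes fasciculatum	Nanzhao, Henan	613	33°33′27″	111°58′04″
A2	Ribes fasciculatum var. chinense	Beijing	88	40°04′32″	116°13′58″
A3	Ribes fasciculatum var. chinense	Dalian, Liaoning	352	38°50′21″	121°26′58″
B1	Ribes heterotrichum	Fuhai, Xinjiang	916	47°34′59″	88°44′36″
B2	Ribes komarovii	Lishan, Shanxi	2358	35°24′58″	111°59′12″
B3	Ribes alpinum	Beijing	88	40°04′32″	116°13′58″
B4	Ribes giraldii var. polyanthum	Dalian, Liaoning	105	39°06′05″	122°00′03″
B5	Ribes pseudofasciculatum	Xining, Qinghai	2332	36°56′37″	102°27′49″
B6	Ribes takare var. desmocarpum	Zhouqu, Gansu	2578	33°43′50″	104°06′12″
B7	Ribes kialanum	Lijiang, Yunnan	3812	27°01′34″	100°10′43″
B8	Ribes tenue	Hezheng, Gansu	2684	35°15′14″	103°14′27″
B9	Ribes tenue	Xining, Qinghai	2518	35°47′37″	102°40′37″
B10	Ribes laurifolium var. yunnanense	Leshan, Sichuan	3099	29°34′26″	103°21′23″
B11	Ribes laurifolium var. yunnanense	Leshan, Sichuan	3099	29°34′26″	103°21′23″
B12	Ribes hunanense	Chengbu, Hunan	1669	26°09′39″	110°11′34″
B13	Ribes laurifolium	Leshan, Sichuan	3099	29°34′26″	103°21′23″
B14	Ribes davidii	Nanchuan, Chongqing	726	29°03′19″	107°08′04″
B15	Ribes davidii	Nanchuan, Chongqing	726	29°03′19″	107°08′04″
C1	Ribes aciculare	Burqin, Xinjiang	1240	48°12′29″	87°37′10″
C2	Ribes aciculare	Fuhai, Xinjiang	916	47°34′59″	88°44′36″
C3	Ribes burejense	Nanzhao, Henan	1349	33°32′04″	111°57′28″
C4	Ribes stenocarpum	Xining, Qinghai	2332	36°56′37″	102°27′49″
C5	Ribes stenocarpum	Guyuan, Ningxia	2928	35°21′51″	106°19′54″
D1	Ribes fragrans	Moerdaoga, Inner Mongolia	1256	51°22′43″	120°49′48″
D2	Ribes procumbens	Daxing’anling, Heilongjiang	1001	52°20′28″	124°42′12″
D3	Ribes nigrum	Hemu, Xinjiang	1389	48°34′27″	87°21′32″
D4	Ribes procumbens	Xiniuerhe, Inner Mongolia	707	51°15′51″	120°47′29″
D5	Ribes nigrum	Ergun, Inner Mongolia	1404	51°09′19″	120°54′37″
E1	Ribes griffithii	Lijiang, Yunnan	3812	27°01′34″	100°10′43″
F1	Ribes palczewskii	Hemu, Xinjiang	1099	48°34′13″	87°25′43″
F2	Ribes tenue	Moerdaoga, Inner Mongolia	869	51°09′19″	120°54′37″
F3	Ribes palczewskii	Xiniuerhe, Inner Mongolia	533	51°52′41″	120°37′56″
F4	Ribes palczewskii	Ergun, Inner Mongolia	1404	51°09′19″	120°54′37″
F5	Ribes moupinense	Kunming, Yunnan	3419	26°04′46″	102°50′05″
F6	Ribes setchuense	Zhouqu, Gansu	2705	33°39′45″	104°09′41″
F7	Ribes setchuense	Zhouqu, Gansu	2705	33°39′45″	104°09′41″
F8	Ribes setchuense	Hezheng, Gansu	2684	35°15′14″	103°14′27″
F9	Ribes setchuense	Hezheng, Gansu	2684	35°15′14″	103°14′27″
F10	Ribes mandshuricum	Nanzhao, Henan	1372	33°21′11″	111°57′17″
F11	Ribes mandshuricum	Guyuan, Ningxia	2928	35°21′51″	106°19′54″
F12	Ribes longiracemosum	Baoji, Shaanxi	568	34°21′22″	107°18′21″
F13	Ribes himalense	Hezheng, Gansu	2684	35°15′14″	103°14′27″
F14	Ribes himalense	Xining, Qinghai	2332	36°56′37″	102°27′49″
F15	Ribes himalense	Xining, Qinghai	2229	35°48′10″	102°40′53″
F16	Ribes himalense	Yinchuan, Ningxia	3556	38°37′54″	106°03′35″
F17	Ribes atropurpureum	Burqin, Xinjiang	1245	48°37′05″	87°30′03″
F18	Ribes atropurpureum	Burqin, Xinjiang	1245	48°37′05″	87°30′03″
F19	Ribes atropurpureum	Fuhai, Xinjiang	1489	47°52′05″	88°56′56″
F20	Ribes altissimum	Hemu, Xinjiang	1446	48°33′07″	87°28′24″
F21	Ribes altissimum	Hemu, Xinjiang	1446	48°33′07″	87°28′24″
F22	Ribes altissimum	Hemu, Xinjiang	1099	48°34′13″	87°25′43″
F23	Ribes altissimum	Hemu, Xinjiang	1099	48°34′13″	87°25′43″
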