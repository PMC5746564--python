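pattern,class
lc urban areas+lc rural settlement,built environment and urban/suburban proxies
lc urban + lc rural,built environment and urban/suburban proxies
lights at night,built environment and urban/suburban proxies
night-time lights,built environment and urban/suburban proxies
nighttime lights,built environment and urban/suburban proxies
night lights,built environment and urban/suburban proxies
building footprints,built environment and urban/suburban proxies
built environment,built environment and urban/suburban proxies
lc nat. and semi-nat. veg.,natural/semi-natural vegetation LC
natural and semi-natural vegetation,natural/semi-natural vegetation LC
semi-natural veg,natural/semi-natural vegetation LC
lc woody,natural/semi-natural vegetation LC
lc shrubs,natural/semi-natural vegetation LC
lc herbaceous,natural/semi-natural vegetation LC
lc aquatic veg,natural/semi-natural vegetation LC
forest cover,natural/semi-natural vegetation LC
lc cultivated,cultivated/managed LC
cultivated terrestrial and managed lands,cultivated/managed LC
cultivated,cultivated/managed LC
cropland,cultivated/managed LC
managed lands,cultivated/managed LC
lc natural bare surface,natural bare surfaces LC
bare surface,natural bare surfaces LC
bare soil,natural bare surfaces LC
lc no data,no data
no data,no data
lu residential,residential LU
residential land use,residential LU
lu industrial,non-residential LU
lu farms,non-residential LU
non-residential land use,non-residential LU
industrial land use,non-residential LU
protected natural areas,protected LU
protected area,protected LU
wdpa,protected LU
classified land uses,general classified LU
general classified land use,general classified LU
land use map,general classified LU
global human settlement layer,urban/suburban extents
ghsl,urban/suburban extents
schneider modis,urban/suburban extents
urban extent,urban/suburban extents
urban/suburban extent,urban/suburban extents
settlement extent,urban/suburban extents
lc urban areas,artificial surface LC
lc rural settlement,artificial surface LC
artificial surface,artificial surface LC
classified populated place,classified populated place
city town village,classified populated place
settlement hierarchy,classified populated place
roads,transportation networks
road,transportation networks
railways,transportation networks
railway,transportation networks
transportation,transportation networks
elevation and slope,climatic/environmental
elevation,climatic/environmental
slope,climatic/environmental
net primary productivity,climatic/environmental
npp,climatic/environmental
temperature,climatic/environmental
precipitation,climatic/environmental
climate,climatic/environmental
schools,facilities and services
school,facilities and services
police,facilities and services
nutrition,facilities and services
health facilities,facilities and services
health facility,facilities and services
hospital,facilities and services
osm places,places and POIs
osm pois,places and POIs
points of interest,places and POIs
poi,places and POIs
lc water,rivers/waterbodies/waterways
rivers,rivers/waterbodies/waterways
river,rivers/waterbodies/waterways
waterbodies,rivers/waterbodies/waterways
waterways,rivers/waterbodies/waterways
water bodies,rivers/waterbodies/waterways
coastline,rivers/waterbodies/waterways
gazetteer,populated place
populated place,populated place
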